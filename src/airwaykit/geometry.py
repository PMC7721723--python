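"""Curved-reformation morphometry along the airway axis.

Given a lumen mask and its centerline, this module measures what a curved
multiplanar reconstruction of the airway yields: cross-sectional areas on
planes perpendicular to the local axis tangent, a station battery anchored
at the caudal edge of the hard palate (labels +3 ... -5 mm, positive =
rostral), the three-segment partition of the airway (nasal cavity / hard
palate / soft palate spans), per-segment volumes, and the pharyngeal length
from the hard palate to the arytenoid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .centerline import Centerline
from .errors import OrderingError, StationRangeError
from .volume import BinaryMask

__all__ = [
    "CrossSection",
    "AirwaySegments",
    "cross_section_at",
    "area_profile",
    "DEFAULT_STATION_OFFSETS_MM",
    "partition_segments",
    "segment_volumes",
    "pharyngeal_length",
]

# the standard nine stations: +3 ... -5 mm at 1 mm intervals, positive rostral
DEFAULT_STATION_OFFSETS_MM = (3.0, 2.0, 1.0, 0.0, -1.0, -2.0, -3.0, -4.0, -5.0)


@dataclass
class CrossSection:
    """One perpendicular-plane measurement."""

    station_label_mm: float          # signed offset from the anchor (positive rostral)
    plane_point_mm: np.ndarray
    plane_normal: np.ndarray         # unit tangent of the centerline at the station
    area_mm2: float
    polygon: np.ndarray | None = None  # (N, 3) boundary contour, world mm
    truncated: bool = False
    missing: bool = False


@dataclass
class AirwaySegments:
    """Arclength positions of the three-segment partition boundaries."""

    s_meatus_merge: float
    s_hard_palate: float
    s_epiglottis: float
    s_end: float

    def __post_init__(self):
        if not (0.0 <= self.s_meatus_merge < self.s_hard_palate
                < self.s_epiglottis <= self.s_end):
            raise OrderingError(
                "segment boundaries must satisfy 0 <= meatus_merge < hard_palate "
                f"< epiglottis <= end, got {self}"
            )


def _plane_basis(normal: np.ndarray):
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def cross_section_at(mask: BinaryMask, centerline: Centerline, s_mm: float,
                     station_label_mm: float | None = None,
                     pitch_mm: float | None = None,
                     half_extent_mm: float | None = None) -> CrossSection:
    """Perpendicular-plane area at arclength ``s_mm``.

    The mask is resampled (nearest neighbor) on a plane through the
    centerline point with normal equal to the local tangent, at sub-voxel
    pitch (default half the voxel spacing).  The area is the in-plane
    4-connected region containing the centerline point, pixel count x pixel
    area.  If the sampling plane is clipped at the volume boundary and the
    region touches the clip, the section is flagged ``truncated`` with a
    warning.
    """
    if not (-1e-9 <= s_mm <= centerline.length_mm + 1e-9):
        raise StationRangeError(
            f"station s={s_mm} mm outside the centerline range "
            f"[0, {centerline.length_mm:.3f}] mm"
        )
    s_mm = float(np.clip(s_mm, 0.0, centerline.length_mm))
    center = np.asarray(centerline.point_at(s_mm), dtype=float)
    normal = centerline.tangent_at(s_mm)
    e1, e2 = _plane_basis(normal)
    pitch = pitch_mm if pitch_mm is not None else 0.5 * float(np.min(mask.spacing_mm))

    if half_extent_mm is None:
        # estimate the local lumen extent from mask voxels in a thin slab
        pts = mask.world_points()
        rel = pts - center
        axial = rel @ normal
        slab = np.abs(axial) < 2.0 * float(np.max(mask.spacing_mm))
        if not slab.any():
            return CrossSection(
                station_label_mm=station_label_mm if station_label_mm is not None else s_mm,
                plane_point_mm=center, plane_normal=normal, area_mm2=0.0, missing=True,
            )
        perp = rel[slab] - np.outer(axial[slab], normal)
        half_extent_mm = float(np.max(np.linalg.norm(perp, axis=1))) + 3 * pitch

    n_pix = int(np.ceil(2 * half_extent_mm / pitch)) + 1
    a = (np.arange(n_pix) - n_pix // 2) * pitch
    A, B = np.meshgrid(a, a, indexing="ij")
    pts_plane = center + A[..., None] * e1 + B[..., None] * e2
    idx = np.rint((pts_plane - mask.origin_mm) / mask.spacing_mm).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=-1)
    plane = np.zeros((n_pix, n_pix), dtype=bool)
    ii = idx[inside]
    plane[inside] = mask.voxels[ii[:, 0], ii[:, 1], ii[:, 2]]

    c = n_pix // 2
    if not plane[c, c]:
        # centerline vertices sit at voxel centers; tolerate half-voxel offsets
        fg = np.argwhere(plane)
        if len(fg) == 0:
            return CrossSection(
                station_label_mm=station_label_mm if station_label_mm is not None else s_mm,
                plane_point_mm=center, plane_normal=normal, area_mm2=0.0, missing=True,
            )
        d2 = np.sum((fg - [c, c]) ** 2, axis=1)
        near = fg[np.argmin(d2)]
        if d2.min() > (2.0 * float(np.max(mask.spacing_mm)) / pitch) ** 2:
            warnings.warn(f"centerline point at s={s_mm:.2f} mm is off-lumen")
        c_idx = tuple(near)
    else:
        c_idx = (c, c)

    labels = cc_label(plane, connectivity=1)
    region = labels == labels[c_idx]
    area = float(np.count_nonzero(region)) * pitch**2

    from scipy.ndimage import binary_dilation

    border = np.zeros_like(region)
    border[[0, -1], :] = True
    border[:, [0, -1]] = True
    grown = binary_dilation(region)
    truncated = bool((grown & ~inside).any() or (region & border).any())
    if truncated:
        warnings.warn(
            f"cross-section at s={s_mm:.2f} mm clipped at the volume boundary; "
            "area computed over the in-volume part"
        )

    polygon = None
    try:
        from skimage.measure import find_contours

        contours = find_contours(region.astype(float), 0.5)
        if contours:
            longest = max(contours, key=len)
            uv = (longest - n_pix // 2) * pitch
            polygon = center + uv[:, 0:1] * e1 + uv[:, 1:2] * e2
    except Exception:  # pragma: no cover - contouring is cosmetic
        polygon = None

    return CrossSection(
        station_label_mm=station_label_mm if station_label_mm is not None else s_mm,
        plane_point_mm=center, plane_normal=normal, area_mm2=area,
        polygon=polygon, truncated=truncated,
    )


def area_profile(mask: BinaryMask, centerline: Centerline, s_anchor_mm: float,
                 offsets_mm=DEFAULT_STATION_OFFSETS_MM, **kwargs) -> list:
    """Cross-sections at labeled stations around an anchor, rostral to caudal.

    Station labels are signed offsets from the anchor with positive = rostral,
    so the section for label ``o`` is taken at arclength ``s_anchor - o``
    (arclength grows rostral -> caudal).  Stations outside the centerline
    range are returned flagged ``missing``; the others are measured.
    """
    sections = []
    for off in offsets_mm:
        s = s_anchor_mm - off
        if not (0.0 <= s <= centerline.length_mm):
            sections.append(
                CrossSection(
                    station_label_mm=off,
                    plane_point_mm=np.full(3, np.nan),
                    plane_normal=np.full(3, np.nan),
                    area_mm2=float("nan"), missing=True,
                )
            )
            continue
        sections.append(
            cross_section_at(mask, centerline, s, station_label_mm=off, **kwargs)
        )
    return sections


def profile_to_dataframe(sections) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            station_label_mm=[s.station_label_mm for s in sections],
            area_mm2=[s.area_mm2 for s in sections],
            truncated=[s.truncated for s in sections],
            missing=[s.missing for s in sections],
        )
    )


def partition_segments(centerline: Centerline, landmarks,
                       pharyngeal_extent_mm: float = 5.0) -> AirwaySegments:
    """Project the three dividing landmarks onto the centerline.

    ``landmarks`` is a mapping (or LandmarkSet) providing ``meatus_merge``,
    ``hard_palate_edge`` and ``epiglottis`` world points; each is projected
    to its nearest centerline point.  ``s_end`` is capped at
    ``s_hard_palate + pharyngeal_extent_mm`` (the conventional caudal limit
    of volume accounting, 5 mm past the hard palate) or the centerline end,
    whichever is rostral.  Out-of-order projections raise OrderingError.
    """
    get = landmarks.get if hasattr(landmarks, "get") else landmarks.__getitem__
    s = {}
    for name in ("meatus_merge", "hard_palate_edge", "epiglottis"):
        p = get(name)
        if p is None:
            raise OrderingError(f"landmark {name} missing")
        s[name] = centerline.project_point(np.asarray(p, dtype=float))
    s_end = min(centerline.length_mm, s["hard_palate_edge"] + pharyngeal_extent_mm)
    return AirwaySegments(
        s_meatus_merge=s["meatus_merge"],
        s_hard_palate=s["hard_palate_edge"],
        s_epiglottis=min(s["epiglottis"], s_end),
        s_end=s_end,
    )


def segment_volumes(mask: BinaryMask, centerline: Centerline,
                    segments: AirwaySegments):
    """(v_nasal, v_pharyngeal, v_total) in mm^3.

    Every mask voxel is assigned to the arclength of its nearest centerline
    point; the nasal volume spans the nostrils to the hard palate, the
    pharyngeal volume the hard palate to ``s_end`` (hard palate + 5 mm), and
    the total is their sum — additive exactly, by construction.
    """
    s_vox = centerline.nearest_arclength(mask.world_points())
    vv = mask.voxel_volume_mm3
    v_nasal = float(np.count_nonzero(s_vox < segments.s_hard_palate)) * vv
    v_phar = float(
        np.count_nonzero((s_vox >= segments.s_hard_palate) & (s_vox <= segments.s_end))
    ) * vv
    return v_nasal, v_phar, v_nasal + v_phar


def pharyngeal_length(centerline: Centerline, s_hard_palate_mm: float,
                      s_arytenoid_mm: float) -> float:
    """Arclength from the hard-palate edge to the arytenoid (mm)."""
    for name, s in (("hard palate", s_hard_palate_mm), ("arytenoid", s_arytenoid_mm)):
        if not (0.0 <= s <= centerline.length_mm + 1e-9):
            raise StationRangeError(f"{name} station {s} mm off the centerline")
    if s_arytenoid_mm < s_hard_palate_mm:
        raise OrderingError("arytenoid must lie caudal to the hard palate")
    return float(s_arytenoid_mm - s_hard_palate_mm)
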