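"""Synthetic phantoms with analytic ground truth.

The study data this package targets (rodent upper-airway micro-CT, breathing
traces, two-group morphometry tables) are not publicly deposited, so every
algorithm here is validated against phantoms whose geometry, waveform
parameters or sampling moments are known exactly:

* voxel airway lumens — straight tube, venturi (tube-taper-throat-taper-tube),
  curved (quarter-torus) tube, and a parametric "mouse upper airway" with the
  six functional landmarks that anchor segment boundaries;
* breathing traces — half-sine inspiration / expiration with known tidal
  volume, rate, inspiratory-time fraction, plus injected noise and movement
  epochs;
* morphometry cohorts — per-measure normal draws with specified group
  moments, mirroring the (mean, SD, n) structure of published tables.

CT-like intensities follow a fixed three-level model (lumen -1000, soft
tissue 0, bone +1000 in HU-like units) so the intensity-inversion +
threshold segmentation route can be exercised.  All generators are pure
functions of (parameters, seed).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.spatial import cKDTree

from .errors import GenerationError, ParameterError
from .morphometry import DEFAULT_PAIR_MAP, DistanceTable, LandmarkSet
from .plethysmography import BreathTrace
from .volume import BinaryMask, Volume3D, save_mask, save_volume

__all__ = [
    "PhantomGroundTruth",
    "BreathSpec",
    "CohortSpec",
    "MouseAirwayConfig",
    "make_tube_phantom",
    "make_venturi_phantom",
    "make_curved_tube_phantom",
    "make_tilted_tube_mask",
    "make_mouse_airway_phantom",
    "make_breath_trace",
    "make_morphometry_cohort",
    "write_phantom",
]

HU_LUMEN = -1000.0
HU_SOFT = 0.0
HU_BONE = 1000.0

DEFAULT_SPACING_MM = 0.02  # matches a 20 um micro-CT reconstruction voxel


@dataclass
class PhantomGroundTruth:
    """Analytic ground truth accompanying a generated phantom."""

    shape_kind: str
    area_profile_true: np.ndarray  # (N, 2): arclength mm, area mm^2
    volume_true_mm3: float
    length_true_mm: float
    landmark_truth: dict = field(default_factory=dict)
    segment_volumes_mm3: dict = field(default_factory=dict)
    pharyngeal_length_mm: float | None = None

    def __post_init__(self):
        self.area_profile_true = np.asarray(self.area_profile_true, dtype=float)
        s, a = self.area_profile_true[:, 0], self.area_profile_true[:, 1]
        if not np.all(np.diff(s) > 0):
            raise GenerationError("ground-truth arclengths must be strictly increasing")
        if not np.all(a > 0):
            raise GenerationError("ground-truth areas must be positive")
        if self.volume_true_mm3 <= 0:
            raise GenerationError("ground-truth volume must be positive")

    def area_at(self, s_mm) -> np.ndarray:
        prof = self.area_profile_true
        return np.interp(s_mm, prof[:, 0], prof[:, 1])

    def integrated_volume_mm3(self) -> float:
        prof = self.area_profile_true
        return float(np.trapezoid(prof[:, 1], prof[:, 0]))

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["area_profile_true"] = self.area_profile_true.tolist()
        d["landmark_truth"] = {k: np.asarray(v).tolist() for k, v in self.landmark_truth.items()}
        return d


def _check_positive(**kwargs):
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ParameterError(f"{name} must be positive, got {value!r}")


def _warn_if_coarse(diameter_mm: float, spacing_mm: float):
    if diameter_mm / spacing_mm < 8:
        warnings.warn(
            f"only {diameter_mm / spacing_mm:.1f} voxels span the diameter; "
            "areas and flow will be poorly resolved (want >= 8)",
            stacklevel=3,
        )


def _intensity_from_mask(mask_vox: np.ndarray, dist_mm: np.ndarray | None,
                         lumen_r: np.ndarray | float | None) -> np.ndarray:
    """Three-level CT-like intensity: lumen, a thin bone shell, soft tissue."""
    vox = np.full(mask_vox.shape, HU_SOFT, dtype=np.float32)
    vox[mask_vox] = HU_LUMEN
    if dist_mm is not None and lumen_r is not None:
        shell = (~mask_vox) & (dist_mm >= lumen_r + 0.08) & (dist_mm < lumen_r + 0.22)
        vox[shell] = HU_BONE
    return vox


_AXES = {"x": 0, "y": 1, "z": 2}


def make_tube_phantom(radius_mm: float, length_mm: float,
                      spacing_mm: float = DEFAULT_SPACING_MM,
                      axis_direction: str = "z"):
    """Solid circular cylinder open at both end faces.

    Returns ``(Volume3D, BinaryMask, PhantomGroundTruth)``.  The intensity
    volume carries the three-level CT model so segmentation can be tested;
    the truth records the analytic area pi r^2, volume pi r^2 L and length.
    """
    _check_positive(radius_mm=radius_mm, length_mm=length_mm, spacing_mm=spacing_mm)
    if axis_direction not in _AXES:
        raise ParameterError(f"axis_direction must be one of {list(_AXES)}")
    _warn_if_coarse(2 * radius_mm, spacing_mm)

    axis = _AXES[axis_direction]
    margin = max(0.45, 4 * spacing_mm)
    n_axis = max(2, int(round(length_mm / spacing_mm)))
    n_cross = int(round(2 * (radius_mm + margin) / spacing_mm))
    shape = [n_cross, n_cross, n_cross]
    shape[axis] = n_axis
    coords = [(np.arange(n) + 0.0) * spacing_mm for n in shape]
    cross_axes = [a for a in range(3) if a != axis]
    centers = [coords[a][len(coords[a]) // 2] for a in cross_axes]
    grids = np.meshgrid(*coords, indexing="ij")
    dist = np.sqrt((grids[cross_axes[0]] - centers[0]) ** 2
                   + (grids[cross_axes[1]] - centers[1]) ** 2)
    mask_vox = dist <= radius_mm
    vox = _intensity_from_mask(mask_vox, dist, radius_mm)

    spacing = np.full(3, spacing_mm)
    origin = np.zeros(3)
    area = np.pi * radius_mm**2
    s = np.linspace(0.0, n_axis * spacing_mm, 9)
    truth = PhantomGroundTruth(
        shape_kind="tube",
        area_profile_true=np.column_stack([s, np.full_like(s, area)]),
        volume_true_mm3=area * n_axis * spacing_mm,
        length_true_mm=n_axis * spacing_mm,
    )
    return (
        Volume3D(vox, spacing, origin),
        BinaryMask(mask_vox, spacing, origin),
        truth,
    )


def make_venturi_phantom(r_inlet_mm: float, r_throat_mm: float,
                         l_inlet_mm: float = 3.0, l_throat_mm: float = 2.0,
                         l_outlet_mm: float = 3.0, taper_len_mm: float = 1.5,
                         spacing_mm: float = DEFAULT_SPACING_MM):
    """Axisymmetric tube-taper-throat-taper-tube along z.

    The ground-truth area profile is non-increasing through the inlet taper,
    constant (and minimal) in the throat, and non-decreasing through the
    outlet taper — the constriction analog of a narrowed airway.
    """
    _check_positive(r_inlet_mm=r_inlet_mm, r_throat_mm=r_throat_mm,
                    l_inlet_mm=l_inlet_mm, l_throat_mm=l_throat_mm,
                    l_outlet_mm=l_outlet_mm, taper_len_mm=taper_len_mm,
                    spacing_mm=spacing_mm)
    if r_throat_mm >= r_inlet_mm:
        raise ParameterError("throat radius must be smaller than inlet radius")
    _warn_if_coarse(2 * r_throat_mm, spacing_mm)

    length = l_inlet_mm + taper_len_mm + l_throat_mm + taper_len_mm + l_outlet_mm
    breaks = np.cumsum([0.0, l_inlet_mm, taper_len_mm, l_throat_mm, taper_len_mm, l_outlet_mm])

    def radius_at(s):
        s = np.asarray(s, dtype=float)
        r = np.full(s.shape, r_inlet_mm)
        t = np.clip((s - breaks[1]) / taper_len_mm, 0, 1)
        r = r_inlet_mm + (r_throat_mm - r_inlet_mm) * t
        t2 = np.clip((s - breaks[3]) / taper_len_mm, 0, 1)
        r = r + (r_inlet_mm - r_throat_mm) * t2
        return r

    margin = max(0.45, 4 * spacing_mm)
    n_z = max(2, int(round(length / spacing_mm)))
    n_cross = int(round(2 * (r_inlet_mm + margin) / spacing_mm))
    x = (np.arange(n_cross)) * spacing_mm
    cx = x[n_cross // 2]
    z = (np.arange(n_z)) * spacing_mm
    X, Y = np.meshgrid(x, x, indexing="ij")
    dist = np.sqrt((X - cx) ** 2 + (Y - cx) ** 2)  # (nx, ny)
    r_z = radius_at(z)  # (nz,)
    mask_vox = dist[:, :, None] <= r_z[None, None, :]
    vox = _intensity_from_mask(mask_vox, np.broadcast_to(dist[:, :, None], mask_vox.shape),
                               r_z[None, None, :])

    s_fine = np.linspace(0.0, n_z * spacing_mm, max(101, 2 * n_z + 1))
    a_fine = np.pi * radius_at(np.minimum(s_fine, length)) ** 2
    spacing = np.full(3, spacing_mm)
    truth = PhantomGroundTruth(
        shape_kind="venturi",
        area_profile_true=np.column_stack([s_fine, a_fine]),
        volume_true_mm3=float(np.trapezoid(a_fine, s_fine)),
        length_true_mm=n_z * spacing_mm,
        landmark_truth={"throat_center": np.array([cx, cx, breaks[2] + 0.5 * l_throat_mm])},
    )
    return Volume3D(vox, spacing, np.zeros(3)), BinaryMask(mask_vox, spacing, np.zeros(3)), truth


def make_tilted_tube_mask(radius_mm: float = 0.5, length_mm: float = 3.0,
                          spacing_mm: float = DEFAULT_SPACING_MM,
                          tilt_deg: float = 30.0) -> BinaryMask:
    """Cylinder mask whose axis is tilted ``tilt_deg`` from the z grid axis.

    The oblique-section oracle: a perpendicular cross-section has area
    pi r^2 while an axial grid slice cuts the ellipse pi r^2 / cos(tilt) —
    the pair distinguishes true curved-reformation measurements from naive
    slice areas.  The axis passes through ``(r + 0.3, extent_y/2, 0)``.
    """
    _check_positive(radius_mm=radius_mm, length_mm=length_mm, spacing_mm=spacing_mm)
    t = np.deg2rad(tilt_deg)
    axis = np.array([np.sin(t), 0.0, np.cos(t)])
    extent_x = length_mm * abs(axis[0]) + 2 * (radius_mm + 0.3)
    extent_y = 2 * (radius_mm + 0.3)
    extent_z = length_mm * axis[2]
    shape = tuple(int(round(e / spacing_mm)) for e in (extent_x, extent_y, extent_z))
    center0 = np.array([radius_mm + 0.3, extent_y / 2, 0.0])
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1) * spacing_mm
    rel = pts - center0
    proj = rel @ axis
    d2 = np.sum(rel**2, axis=-1) - proj**2
    return BinaryMask(d2 <= radius_mm**2, np.full(3, spacing_mm), np.zeros(3))


def make_curved_tube_phantom(tube_radius_mm: float, bend_radius_mm: float,
                             spacing_mm: float = DEFAULT_SPACING_MM):
    """Quarter-torus tube: a constant-section duct bent through 90 degrees.

    The centerline is the circular arc of radius ``bend_radius_mm`` in the
    x-z plane; analytic length is pi R / 2 and the volume follows Pappus's
    theorem (area x centerline length).  Ends open through the z=0 and x=0
    domain faces.
    """
    _check_positive(tube_radius_mm=tube_radius_mm, bend_radius_mm=bend_radius_mm,
                    spacing_mm=spacing_mm)
    if bend_radius_mm <= tube_radius_mm:
        raise ParameterError("bend radius must exceed the tube radius")
    _warn_if_coarse(2 * tube_radius_mm, spacing_mm)

    r, R = tube_radius_mm, bend_radius_mm
    margin = max(0.45, 4 * spacing_mm)
    n_xz = int(round((R + r + margin) / spacing_mm))
    n_y = int(round(2 * (r + margin) / spacing_mm))
    x = np.arange(n_xz) * spacing_mm
    y = np.arange(n_y) * spacing_mm
    y0 = y[n_y // 2]
    X, Y, Z = np.meshgrid(x, y, x, indexing="ij")
    rho = np.sqrt(X**2 + Z**2)
    dist = np.sqrt((rho - R) ** 2 + (Y - y0) ** 2)
    mask_vox = dist <= r
    vox = _intensity_from_mask(mask_vox, dist, r)

    area = np.pi * r**2
    length = np.pi * R / 2
    s = np.linspace(0.0, length, 9)
    spacing = np.full(3, spacing_mm)
    truth = PhantomGroundTruth(
        shape_kind="curved_tube",
        area_profile_true=np.column_stack([s, np.full_like(s, area)]),
        volume_true_mm3=area * length,
        length_true_mm=length,
        landmark_truth={
            "end_a": np.array([R, y0, 0.0]),
            "end_b": np.array([0.0, y0, R]),
        },
    )
    return Volume3D(vox, spacing, np.zeros(3)), BinaryMask(mask_vox, spacing, np.zeros(3)), truth


# ---------------------------------------------------------------------------
# parametric mouse upper airway


@dataclass
class MouseAirwayConfig:
    """Parameters of the parametric mouse upper-airway phantom.

    The phantom is functional, not anatomical: a lumen whose cross-sectional
    area follows interpolated control points along an axis, with the six
    landmarks that matter to the analysis (nostrils, merge of the left/right
    nasopharyngeal meatuses, caudal edge of the hard palate, epiglottis,
    arytenoid).  Defaults give airway-scale numbers: nasal volume ~18 mm^3,
    pharyngeal length 5.8 mm, a nadir of the area profile 1 mm caudal to the
    hard palate.
    """

    spacing_mm: float = DEFAULT_SPACING_MM
    total_length_mm: float = 16.0
    s_meatus_merge_mm: float = 4.0
    s_hard_palate_mm: float = 9.0
    s_epiglottis_mm: float = 14.5
    s_arytenoid_mm: float = 14.8
    # (arclength mm, area mm^2) control points, pchip-interpolated
    area_control_points: tuple = (
        (0.0, 2.2), (2.0, 2.4), (4.0, 2.2), (6.0, 2.0), (8.0, 1.6),
        (9.0, 1.2), (10.0, 0.75), (11.0, 0.85), (12.0, 1.05), (13.0, 1.15),
        (14.0, 1.10), (15.0, 1.00), (16.0, 0.95),
    )
    scale_factor: float = 1.0   # uniform scaling of cross-sections (areas x factor^2)
    curvature_deg: float = 0.0  # total in-plane bend of the axis
    nasal_split: bool = False   # split the rostral lumen into left/right passages

    def validate(self):
        _check_positive(spacing_mm=self.spacing_mm, total_length_mm=self.total_length_mm,
                        scale_factor=self.scale_factor)
        order = (0.0, self.s_meatus_merge_mm, self.s_hard_palate_mm,
                 self.s_epiglottis_mm, self.s_arytenoid_mm)
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ParameterError("landmark arclengths must be strictly increasing")
        if self.s_arytenoid_mm > self.total_length_mm:
            raise ParameterError("arytenoid station beyond the phantom length")


def _mouse_centerline(cfg: MouseAirwayConfig, ds: float):
    """Arclength-sampled axis points and the lateral unit vector (global x)."""
    s = np.arange(0.0, cfg.total_length_mm + 0.5 * ds, ds)
    s[-1] = cfg.total_length_mm
    if cfg.curvature_deg == 0.0:
        y = np.zeros_like(s)
        z = s.copy()
    else:
        phi = np.deg2rad(cfg.curvature_deg) * s / cfg.total_length_mm
        # heading rotates linearly with arclength -> a clothoid-like gentle bend
        z = np.concatenate([[0.0], np.cumsum(np.cos(0.5 * (phi[1:] + phi[:-1])) * np.diff(s))])
        y = np.concatenate([[0.0], np.cumsum(np.sin(0.5 * (phi[1:] + phi[:-1])) * np.diff(s))])
    return s, y, z


def _union_area(r_half: float, separation: float) -> float:
    """Area of the union of two equal circles with center distance ``separation``."""
    a_circle = np.pi * r_half**2
    d = separation
    if d >= 2 * r_half:
        return 2 * a_circle
    if d <= 0:
        return a_circle
    lens = 2 * r_half**2 * np.arccos(d / (2 * r_half)) - 0.5 * d * np.sqrt(
        4 * r_half**2 - d**2
    )
    return 2 * a_circle - lens


def make_mouse_airway_phantom(config: MouseAirwayConfig | None = None, seed: int = 0):
    """Parametric mouse upper-airway phantom.

    Returns ``(Volume3D, BinaryMask, LandmarkSet, PhantomGroundTruth)``.
    The landmark set holds ``nostril_left``, ``nostril_right``,
    ``meatus_merge``, ``hard_palate_edge``, ``epiglottis`` and ``arytenoid``,
    all verified to lie inside the mask (a violation after deformation raises
    :class:`~airwaykit.errors.GenerationError`).  Ground truth carries the
    area profile, total and per-segment volumes, and the pharyngeal length
    (hard palate to arytenoid).
    """
    cfg = config or MouseAirwayConfig()
    cfg.validate()
    h = cfg.spacing_mm
    ds = 0.5 * h
    s_axis, y_axis, z_axis = _mouse_centerline(cfg, ds)

    cps = np.asarray(cfg.area_control_points, dtype=float)
    area_fn = PchipInterpolator(cps[:, 0], cps[:, 1], extrapolate=True)

    def area_single(s):
        return np.maximum(area_fn(np.clip(s, cps[0, 0], cps[-1, 0])), 0.05) * cfg.scale_factor**2

    r_single = np.sqrt(area_single(s_axis) / np.pi)
    r_half = r_single / np.sqrt(2.0)
    # per-side center offset; 1.2 r_half leaves a septum gap at the nostrils
    sep0 = 1.2 * float(r_half[0])
    split_frac = np.clip(1.0 - s_axis / cfg.s_meatus_merge_mm, 0.0, 1.0)
    offset = sep0 * split_frac if cfg.nasal_split else np.zeros_like(s_axis)

    r_max = float(r_single.max())
    margin = max(0.4, 4 * h)
    x_half = r_max + (sep0 if cfg.nasal_split else 0.0) + margin
    y_min = float(y_axis.min()) - r_max - margin
    y_max = float(y_axis.max()) + r_max + margin
    n_x = int(round(2 * x_half / h))
    n_y = int(round((y_max - y_min) / h))
    n_z = int(round(z_axis[-1] / h))
    origin = np.array([-x_half, y_min, 0.0])
    spacing = np.full(3, h)

    xs = origin[0] + np.arange(n_x) * h
    ys = origin[1] + np.arange(n_y) * h
    zs = origin[2] + np.arange(n_z) * h
    cl_pts = np.column_stack([np.zeros_like(s_axis), y_axis, z_axis])
    tree = cKDTree(cl_pts)

    mask_vox = np.zeros((n_x, n_y, n_z), dtype=bool)
    dist_min = np.full((n_x, n_y, n_z), np.inf, dtype=np.float32)
    chunk = max(1, int(2e6 / (n_x * n_y)))
    for k0 in range(0, n_z, chunk):
        k1 = min(n_z, k0 + chunk)
        X, Y, Z = np.meshgrid(xs, ys, zs[k0:k1], indexing="ij")
        pts = np.column_stack([np.zeros(X.size), Y.ravel(), Z.ravel()])
        # nearest axis sample in the bend plane gives the local arclength
        _, idx = tree.query(pts, workers=-1)
        rs = r_single[idx] if not cfg.nasal_split else None
        cx = cl_pts[idx]
        if cfg.nasal_split:
            off = offset[idx]
            rh = np.where(off > 0, r_half[idx], r_single[idx])
            dl = np.sqrt((X.ravel() - (cx[:, 0] - off)) ** 2 + (Y.ravel() - cx[:, 1]) ** 2
                         + (Z.ravel() - cx[:, 2]) ** 2)
            dr = np.sqrt((X.ravel() - (cx[:, 0] + off)) ** 2 + (Y.ravel() - cx[:, 1]) ** 2
                         + (Z.ravel() - cx[:, 2]) ** 2)
            d = np.minimum(dl, dr)
            inside = d <= rh
            radial = rh
        else:
            d = np.sqrt((X.ravel() - cx[:, 0]) ** 2 + (Y.ravel() - cx[:, 1]) ** 2
                        + (Z.ravel() - cx[:, 2]) ** 2)
            inside = d <= rs
            radial = rs
        mask_vox[:, :, k0:k1] = inside.reshape(X.shape)
        dist_min[:, :, k0:k1] = (d - radial).reshape(X.shape).astype(np.float32)

    # intensity: lumen dark, thin bone shell around it, soft tissue elsewhere
    vox = np.full(mask_vox.shape, HU_SOFT, dtype=np.float32)
    vox[mask_vox] = HU_LUMEN
    vox[(~mask_vox) & (dist_min >= 0.08) & (dist_min < 0.22)] = HU_BONE

    mask = BinaryMask(mask_vox, spacing, origin)
    volume = Volume3D(vox, spacing, origin)

    def axis_point(s):
        return np.array([0.0, np.interp(s, s_axis, y_axis), np.interp(s, s_axis, z_axis)])

    nostril_off = offset[0] if cfg.nasal_split else 0.4 * r_single[0]
    landmarks = {
        "nostril_left": axis_point(2 * h) + np.array([-nostril_off, 0, 0]),
        "nostril_right": axis_point(2 * h) + np.array([nostril_off, 0, 0]),
        "meatus_merge": axis_point(cfg.s_meatus_merge_mm),
        "hard_palate_edge": axis_point(cfg.s_hard_palate_mm),
        "epiglottis": axis_point(cfg.s_epiglottis_mm),
        "arytenoid": axis_point(cfg.s_arytenoid_mm),
    }
    for name, p in landmarks.items():
        idx = mask.world_to_index(p)
        if not mask.contains_index(idx) or not mask.voxels[tuple(idx)]:
            raise GenerationError(f"landmark {name} fell outside the mask")

    if cfg.nasal_split:
        a_true = np.array([
            _union_area(rh, 2 * off) if off > 0 else np.pi * r_s**2
            for rh, off, r_s in zip(r_half, offset, r_single)
        ])
    else:
        a_true = np.pi * r_single**2
    profile = np.column_stack([s_axis, a_true])
    s_hp = cfg.s_hard_palate_mm
    s_end = min(s_hp + 5.0, cfg.total_length_mm)

    def seg_volume(s0, s1):
        sel = (s_axis >= s0) & (s_axis <= s1)
        return float(np.trapezoid(a_true[sel], s_axis[sel]))

    truth = PhantomGroundTruth(
        shape_kind="mouse_airway",
        area_profile_true=profile,
        volume_true_mm3=float(np.trapezoid(a_true, s_axis)),
        length_true_mm=cfg.total_length_mm,
        landmark_truth={k: v.copy() for k, v in landmarks.items()},
        segment_volumes_mm3={
            "nasal": seg_volume(0.0, s_hp),
            "pharyngeal": seg_volume(s_hp, s_end),
        },
        pharyngeal_length_mm=cfg.s_arytenoid_mm - cfg.s_hard_palate_mm,
    )
    lset = LandmarkSet(points=landmarks, subject_id=f"phantom_seed{seed}", group="phantom")
    return volume, mask, lset, truth


# ---------------------------------------------------------------------------
# breathing traces


@dataclass
class BreathSpec:
    """Waveform parameters of a synthetic breathing trace.

    Defaults reproduce murine quiet breathing at the scale of the study this
    package emulates: with Ti = 80 ms and a peak inspiratory flow of
    5.28 ml/s, the half-sine inspiration integrates to ~0.27 ml.
    """

    tidal_volume_ml: float = 0.269
    rate_bpm: float = 180.0
    ti_fraction: float = 0.24
    duration_s: float = 60.0
    noise_sd: float = 0.0
    movement_epochs: tuple = ()
    seed: int = 0

    def validate(self):
        _check_positive(tidal_volume_ml=self.tidal_volume_ml, rate_bpm=self.rate_bpm,
                        duration_s=self.duration_s)
        if not 0.0 < self.ti_fraction < 1.0:
            raise ParameterError("ti_fraction must lie strictly between 0 and 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


def make_breath_trace(spec: BreathSpec, sampling_hz: float = 1000.0) -> BreathTrace:
    """Half-sine breathing trace with known parameters.

    Inspiration is a positive half-sine of duration ``Ti = ti_fraction / f``
    and amplitude ``pi TV / (2 Ti)`` (so it integrates to the tidal volume);
    expiration is the negative half-sine returning volume to baseline.
    Volume is the cumulative trapezoidal integral of the (noisy) flow, and
    the movement channel is 1 inside ``movement_epochs``.  Identical specs
    and seeds give bit-identical traces.
    """
    spec.validate()
    f = spec.rate_bpm / 60.0
    if sampling_hz < 20.0 * f:
        raise ParameterError(
            f"sampling rate {sampling_hz} Hz below 20x breathing frequency {f:.2f} Hz"
        )
    period = 1.0 / f
    ti = spec.ti_fraction * period
    te = period - ti
    n = int(round(spec.duration_s * sampling_hz))
    t = np.arange(n) / sampling_hz
    tau = np.mod(t, period)
    a_i = np.pi * spec.tidal_volume_ml / (2.0 * ti)
    a_e = np.pi * spec.tidal_volume_ml / (2.0 * te)
    flow = np.where(
        tau < ti,
        a_i * np.sin(np.pi * tau / ti),
        -a_e * np.sin(np.pi * (tau - ti) / te),
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        flow = flow + rng.normal(0.0, spec.noise_sd, size=n)
    from scipy.integrate import cumulative_trapezoid

    volume = np.concatenate([[0.0], cumulative_trapezoid(flow, t)])
    movement = np.zeros(n, dtype=bool)
    for start, end in spec.movement_epochs:
        movement |= (t >= start) & (t < end)
    return BreathTrace(time_s=t, flow_ml_s=flow, volume_ml=volume, movement=movement)


# ---------------------------------------------------------------------------
# morphometry cohorts


@dataclass
class CohortSpec:
    """Two-group sampling moments per measure.

    ``measures`` maps measure id -> (mean_g1, sd_g1, mean_g2, sd_g2) in mm.
    """

    measures: dict
    n_g1: int = 8
    n_g2: int = 7
    seed: int = 0

    def validate(self):
        if self.n_g1 < 2 or self.n_g2 < 2:
            raise ParameterError("each group needs at least 2 subjects")
        for mid, (m1, s1, m2, s2) in self.measures.items():
            if s1 < 0 or s2 < 0:
                raise ParameterError(f"measure {mid}: SDs must be non-negative")

    @classmethod
    def from_reference_table(cls, table: dict, n_g1=8, n_g2=7, seed=0) -> "CohortSpec":
        """Build a spec from a (mean1, sd1, n1, mean2, sd2, n2) summary table."""
        measures = {k: (v[0], v[1], v[3], v[4]) for k, v in table.items()}
        return cls(measures=measures, n_g1=n_g1, n_g2=n_g2, seed=seed)


def make_morphometry_cohort(spec: CohortSpec):
    """Independent normal draws per measure and subject, per group.

    Returns ``(tables_g1, tables_g2)`` — lists of
    :class:`~airwaykit.morphometry.DistanceTable`.  Reproducible under seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    groups = []
    for gname, n, idx in (("group1", spec.n_g1, 0), ("group2", spec.n_g2, 2)):
        draws = {
            mid: rng.normal(vals[idx], vals[idx + 1], size=n)
            for mid, vals in spec.measures.items()
        }
        tables = [
            DistanceTable(
                values={mid: float(draws[mid][i]) for mid in spec.measures},
                subject_id=f"{gname}_s{i:03d}", group=gname,
            )
            for i in range(n)
        ]
        groups.append(tables)
    return tuple(groups)


# ---------------------------------------------------------------------------
# serialization


def write_phantom(volume: Volume3D, mask: BinaryMask, truth: PhantomGroundTruth,
                  out_dir, stem: str = "phantom",
                  landmarks: LandmarkSet | None = None) -> dict:
    """Write volume + mask as NIfTI, ground truth as a JSON sidecar,
    and landmarks (if any) as CSV.  Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out_dir / f"{stem}.nii.gz",
        "mask": out_dir / f"{stem}_mask.nii.gz",
        "truth": out_dir / f"{stem}_truth.json",
    }
    save_volume(volume, paths["volume"])
    save_mask(mask, paths["mask"])
    paths["truth"].write_text(json.dumps(truth.to_json_dict(), indent=2, sort_keys=True))
    if landmarks is not None:
        import pandas as pd

        paths["landmarks"] = out_dir / f"{stem}_landmarks.csv"
        rows = [dict(name=k, x_mm=v[0], y_mm=v[1], z_mm=v[2])
                for k, v in landmarks.points.items()]
        pd.DataFrame(rows).to_csv(paths["landmarks"], index=False)
    return paths
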