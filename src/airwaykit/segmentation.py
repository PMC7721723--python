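"""Airway lumen segmentation from CT-like volumes.

In CT the airway lumen is the most negative structure in the head, so the
standard route to a luminal mask is: invert the intensities (air becomes the
brightest tissue class), threshold — either a fixed value or automatic
bimodal (Otsu) selection — and keep the 26-connected component containing a
seed point placed inside the lumen.  Holes are filled per axial slice so
genuine side channels are not sealed shut.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import SegmentationError
from .volume import BinaryMask, Volume3D

__all__ = ["invert_intensity", "segment_airway", "mask_volume_mm3"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def invert_intensity(volume: Volume3D) -> Volume3D:
    """Negate voxel values (air bright); geometry unchanged. Involution."""
    return Volume3D(
        voxels=-volume.voxels,
        spacing_mm=volume.spacing_mm.copy(),
        origin_mm=volume.origin_mm.copy(),
        axis_labels=volume.axis_labels,
    )


def segment_airway(volume: Volume3D, threshold_mode="otsu",
                   seed_point_mm=None) -> BinaryMask:
    """Threshold + seeded connected component + slice-wise hole filling.

    Parameters
    ----------
    volume
        Inverted volume (lumen bright).
    threshold_mode
        ``"otsu"`` for automatic bimodal selection on the voxel histogram,
        or a numeric value used as a fixed threshold.  Voxels strictly above
        the threshold are foreground, so raising a fixed threshold can never
        add voxels.
    seed_point_mm
        World point inside the intended lumen; only its 26-connected
        component is kept.

    Raises
    ------
    SegmentationError
        If the seed voxel is not inside any above-threshold component.
    """
    if threshold_mode == "otsu":
        threshold = float(threshold_otsu(volume.voxels))
    else:
        threshold = float(threshold_mode)
    fg = volume.voxels > threshold
    if seed_point_mm is None:
        raise SegmentationError("a seed point inside the lumen is required")
    seed_idx = volume.world_to_index(seed_point_mm)
    if not volume.contains_index(seed_idx) or not fg[tuple(seed_idx)]:
        raise SegmentationError(
            f"seed point {np.asarray(seed_point_mm)} (voxel {seed_idx}) is not "
            f"above the threshold {threshold:g}"
        )
    labels, _ = ndimage.label(fg, structure=_CONN26)
    keep = labels == labels[tuple(seed_idx)]
    # fill holes slice by slice along z: keeps genuine 3-D side channels open
    for k in range(keep.shape[2]):
        keep[:, :, k] = ndimage.binary_fill_holes(keep[:, :, k])
    return BinaryMask(voxels=keep, spacing_mm=volume.spacing_mm.copy(),
                      origin_mm=volume.origin_mm.copy())


def mask_volume_mm3(mask: BinaryMask, centerline=None, arclength_range_mm=None) -> float:
    """Mask volume (voxel count x voxel volume), optionally arclength-bounded.

    With ``centerline`` and ``arclength_range_mm=(s0, s1)``, each foreground
    voxel is assigned the arclength of its nearest centerline point and only
    voxels with ``s0 <= s < s1`` are counted.  An empty region returns 0 with
    a warning.
    """
    if arclength_range_mm is None:
        return mask.volume_mm3
    if centerline is None:
        raise ValueError("arclength bounds require a centerline")
    s0, s1 = arclength_range_mm
    if s1 <= s0:
        warnings.warn("empty arclength interval; volume is 0")
        return 0.0
    s_vox = centerline.nearest_arclength(mask.world_points())
    count = int(np.count_nonzero((s_vox >= s0) & (s_vox < s1)))
    if count == 0:
        warnings.warn("no mask voxels inside the requested arclength interval")
    return count * mask.voxel_volume_mm3
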