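"""Voxel-grid containers and volumetric image I/O.

Conventions used throughout the package:

* voxel arrays are indexed ``[i, j, k]`` along axes ``(x, y, z)``;
* indices are 0-based and map to world coordinates at voxel centers,
  ``world = origin_mm + index * spacing_mm``;
* all physical quantities are millimeters.

Reading and writing rides on SimpleITK, which handles NIfTI, MetaImage and
DICOM series natively; DICOM slices are ordered by spatial position (via
GDCM), never by filename.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import FormatError

__all__ = ["Volume3D", "BinaryMask", "load_volume", "save_volume", "save_mask"]


@dataclass
class Volume3D:
    """Scalar voxel grid with physical spacing and origin (mm)."""

    voxels: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    axis_labels: tuple = ("x", "y", "z")

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if self.voxels.ndim != 3:
            raise FormatError("voxel grid must be 3-D")
        if not np.all(self.spacing_mm > 0):
            raise FormatError("voxel spacing must be strictly positive on all axes")

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def index_to_world(self, index) -> np.ndarray:
        """World coordinate (mm) of a voxel index (voxel-center convention)."""
        return self.origin_mm + np.asarray(index, dtype=float) * self.spacing_mm

    def world_to_index(self, point_mm) -> np.ndarray:
        """Nearest voxel index of a world point; may lie outside the grid."""
        return np.rint(
            (np.asarray(point_mm, dtype=float) - self.origin_mm) / self.spacing_mm
        ).astype(int)

    def contains_index(self, index) -> bool:
        index = np.asarray(index)
        return bool(np.all(index >= 0) and np.all(index < self.shape))


@dataclass
class BinaryMask(Volume3D):
    """Boolean voxel grid sharing the geometry of its source volume."""

    def __post_init__(self):
        super().__post_init__()
        self.voxels = self.voxels.astype(bool)

    @property
    def volume_mm3(self) -> float:
        """Total mask volume: voxel count times voxel volume."""
        return float(np.count_nonzero(self.voxels)) * self.voxel_volume_mm3

    def world_points(self) -> np.ndarray:
        """(N, 3) world coordinates of all foreground voxel centers."""
        idx = np.argwhere(self.voxels)
        return self.origin_mm + idx * self.spacing_mm


_IDENTITY = np.eye(3).ravel()


def _from_sitk(img: sitk.Image) -> Volume3D:
    direction = np.asarray(img.GetDirection(), dtype=float)
    if direction.size == 9 and not np.allclose(direction, _IDENTITY, atol=1e-3):
        warnings.warn(
            "non-identity direction matrix; axes are interpreted as stored",
            stacklevel=3,
        )
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return Volume3D(
        voxels=np.ascontiguousarray(arr.transpose(2, 1, 0)),
        spacing_mm=np.asarray(img.GetSpacing(), dtype=float),
        origin_mm=np.asarray(img.GetOrigin(), dtype=float),
    )


def _check_dicom_spacing(files) -> None:
    """Reject series whose slice-to-slice spacing varies by more than 1%."""
    import pydicom

    zs = []
    for f in files:
        ds = pydicom.dcmread(f, stop_before_pixels=True)
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is None:
            return  # position-less series: let GDCM's ordering stand
        zs.append(float(ipp[2]))
    zs = np.sort(np.asarray(zs))
    if len(zs) < 3:
        return
    steps = np.diff(zs)
    mean = steps.mean()
    if mean > 0 and np.max(np.abs(steps - mean)) > 0.01 * mean:
        raise FormatError(
            f"inconsistent DICOM slice spacing (max deviation "
            f"{np.max(np.abs(steps - mean)) / mean:.1%} of mean)"
        )


def load_volume(path) -> Volume3D:
    """Load a NIfTI / MetaImage file or a directory holding one DICOM series.

    DICOM slices are ordered by spatial position. A directory containing more
    than one series UID, or a series with >1% slice-spacing variation, raises
    :class:`~airwaykit.errors.FormatError`.
    """
    path = Path(path)
    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        series_ids = reader.GetGDCMSeriesIDs(str(path))
        if len(series_ids) == 0:
            raise FormatError(f"no DICOM series found in {path}")
        if len(series_ids) > 1:
            raise FormatError(
                f"directory {path} holds {len(series_ids)} DICOM series; "
                "expected exactly one"
            )
        files = reader.GetGDCMSeriesFileNames(str(path), series_ids[0])
        _check_dicom_spacing(files)
        reader.SetFileNames(files)
        try:
            img = reader.Execute()
        except RuntimeError as exc:  # pragma: no cover - GDCM error paths
            raise FormatError(f"could not read DICOM series in {path}: {exc}") from exc
        return _from_sitk(img)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc
    return _from_sitk(img)


def _to_sitk(volume: Volume3D, dtype=None) -> sitk.Image:
    arr = volume.voxels
    if dtype is not None:
        arr = arr.astype(dtype)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing_mm))
    img.SetOrigin(tuple(float(o) for o in volume.origin_mm))
    return img


def save_volume(volume: Volume3D, path) -> None:
    """Write a scalar volume to NIfTI / MetaImage (format from extension)."""
    sitk.WriteImage(_to_sitk(volume), str(path))


def save_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask with a uint8 payload."""
    sitk.WriteImage(_to_sitk(mask, dtype=np.uint8), str(path))


def load_mask(path) -> BinaryMask:
    """Load a mask written by :func:`save_mask` (nonzero voxels = foreground)."""
    vol = load_volume(path)
    return BinaryMask(
        voxels=vol.voxels != 0, spacing_mm=vol.spacing_mm, origin_mm=vol.origin_mm
    )
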