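"""NIfTI I/O for volumes, label maps, and displacement fields.

Volumes are carried as :class:`Volume` objects: a 3D float array plus the
world affine and voxel spacing from the NIfTI header.  The world affine is
preserved on write but never enters the registration math, which operates in
0-based ``(D, H, W)`` voxel index space.  Displacement fields are stored as
4D NIfTI with a trailing vector dimension of size 3, in the normalized
[-1, 1] coordinate convention of :mod:`epreg.transform` (a header note marks
this; converters to voxel units live in the transform module).
"""

from __future__ import annotations

import dataclasses
import os

import nibabel as nib
import numpy as np
from scipy import ndimage

from .transform import identity_grid

__all__ = [
    "Volume",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_field",
    "write_field",
    "preprocess",
]

FIELD_DESCRIP = b"epreg displacement field, normalized [-1,1] coords"


@dataclasses.dataclass
class Volume:
    """A 3D scalar intensity grid with shape metadata."""

    data: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine_meta: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclasses.dataclass
class LabelMap:
    """A 3D integer ROI map; 0 is background."""

    data: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine_meta: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(4))

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected 3D labels, got {data.ndim}D")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("label map values must be integers")
            data = np.round(data).astype(np.int32)
        if data.min() < 0:
            raise ValueError("label values must be non-negative")
        self.data = data.astype(np.int32)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def label_ids(self) -> set[int]:
        return set(int(v) for v in np.unique(self.data) if v != 0)


def _load(path):
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path
        raise IOError(f"could not read NIfTI header of {path}: {exc}") from exc
    return img


def read_volume(path) -> Volume:
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"expected 3D volume in {path}, got {data.ndim}D shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(data, dtype=np.float64), zooms, img.affine)


def write_volume(vol: Volume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine_meta)
    img.header.set_zooms(vol.voxel_spacing)
    nib.save(img, str(path))


def read_labels(path) -> LabelMap:
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"expected 3D label map in {path}, got {data.ndim}D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(data, zooms, img.affine)


def write_labels(labels: LabelMap, path) -> None:
    img = nib.Nifti1Image(labels.data.astype(np.int16), labels.affine_meta)
    nib.save(img, str(path))


def write_field(field: np.ndarray, path, affine: np.ndarray | None = None
                ) -> None:
    """Save a (3, D, H, W) displacement field as 4D NIfTI (vector last)."""
    field = np.asarray(field)
    if field.ndim != 4 or field.shape[0] != 3:
        raise ValueError(f"expected (3, D, H, W) field, got {field.shape}")
    if not np.all(np.isfinite(field)):
        raise ValueError("refusing to write a field with non-finite values")
    arr = np.moveaxis(field.astype(np.float32), 0, -1)
    img = nib.Nifti1Image(arr, affine if affine is not None else np.eye(4))
    img.header["descrip"] = FIELD_DESCRIP
    nib.save(img, str(path))


def read_field(path) -> np.ndarray:
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"expected 4D field with trailing vector dim 3 in {path}, "
            f"got shape {data.shape}")
    return np.moveaxis(np.asarray(data, dtype=np.float64), -1, 0)


def preprocess(vol: Volume, target_shape: tuple[int, int, int]) -> Volume:
    """Resample to ``target_shape`` (trilinear) and min-max normalize to [0,1].

    The network halves the grid four times, so every target axis must be
    divisible by 16 (and at least 16).  A constant-intensity volume maps to
    all zeros (degenerate range).
    """
    target_shape = tuple(int(n) for n in target_shape)
    for n in target_shape:
        if n < 16 or n % 16 != 0:
            raise ValueError(
                f"target shape {target_shape} must have every axis >= 16 and "
                "divisible by 16 (four stride-2 pyramid levels)")
    data = vol.data
    if tuple(data.shape) != target_shape:
        # identity-grid resample in align-corners normalized coordinates,
        # consistent with the warping convention used everywhere else
        grid = identity_grid(target_shape)
        coords = [(grid[ax] + 1.0) * 0.5 * (data.shape[ax] - 1)
                  for ax in range(3)]
        data = ndimage.map_coordinates(data, np.stack(coords), order=1,
                                       mode="nearest")
    lo, hi = float(data.min()), float(data.max())
    if hi > lo:
        data = (data - lo) / (hi - lo)
    else:
        data = np.zeros_like(data)
    spacing = tuple(
        vol.voxel_spacing[i] * (vol.data.shape[i] / target_shape[i])
        for i in range(3))
    return Volume(data, spacing, vol.affine_meta)
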