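"""Synthetic phantoms and ground-truth deformations.

The generator stands in for the skull-stripped, intensity-normalized brain
MRI volumes the method targets: smooth textured backgrounds with a handful
of blob-shaped labeled regions, deformed by a random 12-DOF affine plus a
smooth non-rigid displacement field of controlled amplitude.  The moving
image of a pair is produced by warping the fixed phantom with a known
transform, so recovery experiments have an exact ground truth.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io_nifti import LabelMap, Volume
from .transform import (compose_grid, identity_grid, voxels_to_field, warp,
                        warp_labels_nn, affine_grid)

__all__ = ["PhantomSpec", "DeformationSpec", "make_phantom",
           "make_deformation", "make_pair"]


@dataclasses.dataclass
class PhantomSpec:
    """Labeled 3D phantom parameters.

    shape : volume dimensions in voxels
    n_rois : number of labeled blob regions (>= 1)
    sigma_tex : Gaussian blur of the background texture, voxels
    seed : RNG seed; the phantom is a pure function of it
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    n_rois: int = 4
    sigma_tex: float = 3.0
    seed: int = 0


@dataclasses.dataclass
class DeformationSpec:
    """Ground-truth transform parameters.

    rotation_deg : max |rotation| per axis, degrees
    scale_dev : max |scale - 1| per axis
    translation_frac : max |translation| as a fraction of the half-extent
    amplitude : max displacement norm of the non-rigid part, voxels
    sigma_field : Gaussian smoothness of the non-rigid part, voxels (>= 1)
    seed : RNG seed
    """

    rotation_deg: float = 3.0
    scale_dev: float = 0.03
    translation_frac: float = 0.02
    amplitude: float = 4.0
    sigma_field: float = 8.0
    seed: int = 0


def make_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Smooth textured volume with ``n_rois`` distinct labeled blobs."""
    shape = tuple(int(n) for n in spec.shape)
    if min(shape) < 8:
        raise ValueError(f"phantom shape too small: {shape}")
    if spec.n_rois < 1:
        raise ValueError("need at least one ROI")
    rng = np.random.default_rng(spec.seed)
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), spec.sigma_tex)
    tex = (tex - tex.min()) / (tex.max() - tex.min() + 1e-12)
    vol = 0.15 + 0.2 * tex
    labels = np.zeros(shape, dtype=np.int32)
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape],
                                indexing="ij"), axis=0).astype(np.float64)
    for roi in range(1, spec.n_rois + 1):
        # blob: thresholded smooth random field inside a random ellipsoid
        center = np.array([rng.uniform(0.25 * n, 0.75 * n) for n in shape])
        radius = np.array([rng.uniform(0.1 * n, 0.18 * n) for n in shape])
        dist = (((grid - center.reshape(3, 1, 1, 1))
                 / radius.reshape(3, 1, 1, 1))**2).sum(axis=0)
        bump = ndimage.gaussian_filter(rng.standard_normal(shape), 4.0)
        mask = dist + 0.8 * bump < 1.0
        mask &= labels == 0
        labels[mask] = roi
        vol[mask] = 0.4 + 0.5 * roi / spec.n_rois
    vol = np.clip(ndimage.gaussian_filter(vol, 0.8), 0.0, 1.0)
    return Volume(vol), LabelMap(labels)


def _random_affine(spec: DeformationSpec, rng) -> np.ndarray:
    """Random 3x4 affine on normalized coordinates within spec magnitudes."""
    angles = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg, 3))
    rots = []
    for ax, a in enumerate(angles):
        r = np.eye(3)
        i, j = [k for k in range(3) if k != ax]
        r[i, i] = r[j, j] = np.cos(a)
        r[i, j] = -np.sin(a)
        r[j, i] = np.sin(a)
        rots.append(r)
    lin = rots[0] @ rots[1] @ rots[2]
    lin = lin @ np.diag(1.0 + rng.uniform(-spec.scale_dev, spec.scale_dev, 3))
    trans = rng.uniform(-spec.translation_frac, spec.translation_frac, 3)
    return np.concatenate([lin, trans.reshape(3, 1)], axis=1)


def make_deformation(spec: DeformationSpec, shape: tuple[int, int, int]
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Random ground-truth transform: (3x4 affine, non-rigid field).

    The non-rigid part is Gaussian-smoothed white noise per component,
    rescaled so its maximum displacement norm equals ``amplitude`` voxels,
    returned in normalized coordinates at full resolution.
    """
    if spec.sigma_field < 1:
        raise ValueError("sigma_field must be >= 1 voxel")
    rng = np.random.default_rng(spec.seed)
    affine = _random_affine(spec, rng)
    field_vox = np.stack([
        ndimage.gaussian_filter(rng.standard_normal(shape), spec.sigma_field)
        for _ in range(3)])
    if spec.amplitude > 0:
        norms = np.sqrt((field_vox**2).sum(axis=0))
        peak = norms.max()
        if peak > 0:
            field_vox *= spec.amplitude / peak
    else:
        field_vox[:] = 0.0
    return affine, voxels_to_field(field_vox, shape)


def ground_truth_grid(affine: np.ndarray, nonrigid: np.ndarray,
                      shape: tuple[int, int, int]) -> np.ndarray:
    """Sampling grid of affine followed by the additive non-rigid residual."""
    return affine_grid(affine, shape) + nonrigid


def make_pair(phantom_spec: PhantomSpec, deform_spec: DeformationSpec):
    """Fixed/moving pair with labels and the exact ground-truth grid.

    The moving volume is the fixed phantom warped by the ground-truth grid
    (labels warped nearest-neighbor), so the true correspondence is known
    and field-recovery error can be scored directly.
    """
    vol, labels = make_phantom(phantom_spec)
    affine, nonrigid = make_deformation(deform_spec, vol.shape)
    gt_grid = ground_truth_grid(affine, nonrigid, vol.shape)
    moving = warp(vol.data, gt_grid)
    moving_labels = warp_labels_nn(labels.data, gt_grid)
    return (vol, Volume(moving), labels, LabelMap(moving_labels), gt_grid)
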