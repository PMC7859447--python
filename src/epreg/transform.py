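"""Deformation grids, displacement fields, and trilinear warping.

Coordinate convention used throughout the package: sampling coordinates are
normalized to ``[-1, 1]`` per axis with align-corners semantics (coordinate
-1 is voxel index 0, +1 is index ``n-1``).  Component ``c`` of a grid or
field addresses array axis ``c`` — there is no separate x/y/z relabeling.
A key payoff of this convention is that 2x trilinear upsampling of a grid or
field needs no magnitude rescaling, which makes the additive coarse-to-fine
grid combination well defined at every pyramid level.

Grids and fields are ``(3, D, H, W)`` arrays.  Every function accepts either
plain numpy arrays or autodiff :class:`~epreg.autodiff.Tensor` objects and
returns the same kind; the Tensor path is differentiable.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad

__all__ = [
    "identity_grid",
    "affine_grid",
    "warp",
    "warp_labels_nn",
    "upsample_grid",
    "resize_field",
    "compose_grid",
    "aggregate_field",
    "field_to_voxels",
    "voxels_to_field",
]


def _is_tensor(x) -> bool:
    return isinstance(x, ad.Tensor)


def identity_grid(shape: tuple[int, int, int], dtype=np.float64) -> np.ndarray:
    """Grid mapping every voxel to its own normalized coordinate."""
    axes = []
    for n in shape:
        if n < 1:
            raise ValueError(f"grid axis must be >= 1, got {n}")
        axes.append(np.linspace(-1.0, 1.0, n, dtype=dtype) if n > 1
                    else np.zeros(1, dtype=dtype))
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack(mesh, axis=0)


def affine_grid(matrix, shape: tuple[int, int, int]):
    """Dense sampling grid of a 3x4 affine acting on normalized coordinates.

    ``matrix`` is ``[A | t]`` (12 degrees of freedom); the grid coordinate at
    voxel ``p`` is ``A @ c(p) + t`` where ``c(p)`` is the normalized
    coordinate of ``p``.
    """
    tensor_in = _is_tensor(matrix)
    m = matrix if tensor_in else ad.Tensor(np.asarray(matrix, dtype=np.float64))
    if m.shape != (3, 4):
        raise ValueError(f"affine matrix must be 3x4, got {m.shape}")
    ident = identity_grid(shape)
    coords = np.concatenate(
        [ident.reshape(3, -1), np.ones((1, ident[0].size))],
        axis=0).astype(m.dtype)
    out = ad.matmul(m, ad.Tensor(coords)).reshape((3,) + tuple(shape))
    return out if tensor_in else out.data


def warp(image, grid):
    """Trilinearly resample ``image`` at the absolute coordinates in ``grid``.

    ``image`` may be a plain 3D volume or a channel-first ``(C, D, H, W)``
    feature grid; out-of-domain coordinates clamp to the border.
    """
    tensor_in = _is_tensor(image) or _is_tensor(grid)
    img = image if _is_tensor(image) else ad.Tensor(np.asarray(image))
    g = grid if _is_tensor(grid) else ad.Tensor(np.asarray(grid))
    if g.shape[0] != 3:
        raise ValueError("deformation grid must have 3 vector components")
    squeeze = img.ndim == 3
    if squeeze:
        img = img.reshape((1,) + tuple(img.shape))
    out = ad.grid_sample(img, g)
    if squeeze:
        out = out.reshape(tuple(out.shape[1:]))
    return out if tensor_in else out.data


def warp_labels_nn(labels: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Warp an integer label map with nearest-neighbor sampling.

    Trilinear interpolation would blend label integers, so ROI maps are
    resampled by rounding each sample position to the nearest voxel.
    """
    labels = np.asarray(labels)
    g = grid.data if _is_tensor(grid) else np.asarray(grid)
    idx = []
    for ax, n in enumerate(labels.shape):
        p = (g[ax] + 1.0) * 0.5 * (n - 1)
        idx.append(np.clip(np.rint(p), 0, n - 1).astype(np.intp))
    return labels[idx[0], idx[1], idx[2]]


def resize_field(field, shape: tuple[int, int, int]):
    """Trilinearly resample each component of a grid/field to ``shape``.

    In normalized align-corners coordinates the component values transfer
    between resolutions unchanged (no rescaling of magnitudes).
    """
    tensor_in = _is_tensor(field)
    f = field if tensor_in else ad.Tensor(np.asarray(field))
    out = ad.resize3d(f, tuple(int(n) for n in shape))
    return out if tensor_in else out.data


def upsample_grid(grid, factor: int = 2):
    """Upsample a grid or field by an integer factor (trilinear)."""
    sp = tuple(int(n * factor) for n in grid.shape[1:])
    return resize_field(grid, sp)


def compose_grid(g_coarse, phi, mode: str = "additive"):
    """Finer-level grid from a coarse grid and a residual displacement.

    Default (``additive``): ``G_i = upsample_2(G_{i+1}) + phi_i`` — the
    coarse grid is trilinearly upsampled to the residual's resolution and
    the residual field is added.  ``resample`` instead samples the
    upsampled coarse grid at the residual-displaced positions
    (``G_i(p) = up(G_{i+1})(p + phi_i(p))``), the warp-of-warp composition,
    available for experimentation.
    """
    up = upsample_grid(g_coarse, 2)
    if tuple(up.shape) != tuple(phi.shape):
        raise ValueError(
            f"upsampled grid shape {tuple(up.shape)} does not match "
            f"residual field shape {tuple(phi.shape)}")
    tensor_in = _is_tensor(up) or _is_tensor(phi)
    if mode == "additive":
        return ad.add(up, phi) if tensor_in else up + phi
    if mode == "resample":
        ident = identity_grid(phi.shape[1:])
        sample_at = ad.add(ad.astensor(ident), ad.astensor(phi))
        out = ad.grid_sample(ad.astensor(up), sample_at)
        return out if tensor_in else out.data
    raise ValueError(f"unknown composition mode '{mode}'")


def aggregate_field(phis: dict, full_shape: tuple[int, int, int]):
    """Sum the per-level residual fields at full resolution.

    ``phis`` maps level ``i`` (1..4) to the residual displacement estimated
    at that level; level 4 is the dense affine residual (affine grid minus
    identity).  Each field lives at ``full_shape / 2^i`` and is trilinearly
    upsampled by ``2^i`` before summation, yielding the overall displacement
    the smoothness penalty acts on.
    """
    total = None
    for level, phi in sorted(phis.items()):
        up = resize_field(phi, full_shape)
        total = up if total is None else (
            ad.add(total, up) if (_is_tensor(total) or _is_tensor(up))
            else total + up)
    return total


def field_to_voxels(field, shape=None) -> np.ndarray:
    """Convert a normalized-coordinate displacement field to voxel units."""
    f = field.data if _is_tensor(field) else np.asarray(field)
    shape = shape if shape is not None else f.shape[1:]
    scale = np.array([(n - 1) / 2.0 for n in shape]).reshape(3, 1, 1, 1)
    return f * scale


def voxels_to_field(disp_vox, shape=None) -> np.ndarray:
    """Convert a voxel-unit displacement field to normalized coordinates."""
    d = np.asarray(disp_vox)
    shape = shape if shape is not None else d.shape[1:]
    scale = np.array([2.0 / (n - 1) for n in shape]).reshape(3, 1, 1, 1)
    return d * scale
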