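"""Unsupervised registration objective.

Three pieces: a windowed (patch-based) local normalized cross-correlation
similarity, a diffusion regularizer on the aggregated displacement field,
and the multi-scale total loss that evaluates the similarity at each pyramid
level on correspondingly downsampled image pairs.

A note on the local NCC normalization: the correlation ratio is computed as
``cross² / (var_f · var_w + ε)`` with *squared* centered sums in the
denominator, the standard form for which each local term lies in [0, 1].
The ε term stabilizes locally constant windows where both variances vanish.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .transform import resize_field, warp

__all__ = ["LossConfig", "lncc_loss", "smoothness_loss", "total_loss"]


@dataclasses.dataclass
class LossConfig:
    """Hyperparameters of the training objective.

    window : side of the cubic correlation window, in voxels (odd, >= 3)
    lam : weight of the diffusion regularizer
    eps : stabilizer added to the correlation denominator ([0,1] intensities)
    """

    window: int = 9
    lam: float = 1000.0
    eps: float = 1e-5
    downsample: str = "trilinear"  # or "avgpool"

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.downsample not in ("trilinear", "avgpool"):
            raise ValueError("downsample must be 'trilinear' or 'avgpool'")


def _as4d(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
    if t.ndim == 3:
        t = t.reshape((1,) + tuple(t.shape))
    return t


def lncc_loss(fixed, warped, cfg: LossConfig | None = None):
    """Negative sum of local squared correlation coefficients.

    Window sums are computed with separable sliding box filters under
    edge-replicate padding, so every voxel contributes a full ``v³`` window.
    For a non-constant pair that matches perfectly the loss approaches
    ``-|Ω|``; the value is invariant to positive affine rescaling of either
    image's intensities.
    """
    cfg = cfg or LossConfig()
    f, w = _as4d(fixed), _as4d(warped)
    if tuple(f.shape) != tuple(w.shape):
        raise ValueError(f"shape mismatch: {tuple(f.shape)} vs {tuple(w.shape)}")
    v = cfg.window
    n = float(v**3)
    s_f = ad.box_sum3d(f, v)
    s_w = ad.box_sum3d(w, v)
    s_ff = ad.box_sum3d(ad.mul(f, f), v)
    s_ww = ad.box_sum3d(ad.mul(w, w), v)
    s_fw = ad.box_sum3d(ad.mul(f, w), v)
    cross = s_fw - s_f * s_w * (1.0 / n)
    var_f = s_ff - s_f * s_f * (1.0 / n)
    var_w = s_ww - s_w * s_w * (1.0 / n)
    cc = ad.div(ad.mul(cross, cross), ad.add(ad.mul(var_f, var_w), cfg.eps))
    out = -cc.sum()
    return out if (isinstance(fixed, Tensor) or isinstance(warped, Tensor)) \
        else out.item()


def smoothness_loss(field):
    """Diffusion regularizer: sum of squared forward differences of φ.

    Differences are taken per vector component along each axis; boundary
    voxels without a forward neighbor are excluded (interior sum).
    """
    f = field if isinstance(field, Tensor) else Tensor(np.asarray(field))
    if f.ndim != 4 or f.shape[0] != 3:
        raise ValueError(f"expected (3, D, H, W) field, got {tuple(f.shape)}")
    total = None
    for ax in range(1, 4):
        lo = [slice(None)] * 4
        hi = [slice(None)] * 4
        lo[ax] = slice(None, -1)
        hi[ax] = slice(1, None)
        d = f[tuple(hi)] - f[tuple(lo)]
        term = ad.mul(d, d).sum()
        total = term if total is None else total + term
    return total if isinstance(field, Tensor) else total.item()


def total_loss(fixed, moving, grids: dict, aggregate, cfg: LossConfig | None = None):
    """Multi-scale objective: per-level similarity plus weighted smoothness.

    ``grids`` maps pyramid level ``i`` (1..4) to the deformation grid at that
    level; the fixed and moving volumes are trilinearly downsampled by
    ``2^i`` and the moving side is warped with ``G_i`` before the similarity
    is evaluated.  ``aggregate`` is the full-resolution aggregated field the
    diffusion penalty acts on.  Returns ``(total, breakdown)`` where the
    breakdown maps term names to floats and sums exactly to the total.
    """
    cfg = cfg or LossConfig()
    if sorted(grids.keys()) != [1, 2, 3, 4]:
        raise ValueError(f"grids must cover levels 1..4, got {sorted(grids)}")
    f = fixed if isinstance(fixed, Tensor) else Tensor(np.asarray(fixed))
    m = moving if isinstance(moving, Tensor) else Tensor(np.asarray(moving))
    shape = tuple(f.shape)
    breakdown: dict[str, float] = {}
    total = None

    def down(x, factor, lvl_shape):
        if cfg.downsample == "avgpool":
            c, d, h, w = x.shape
            blocks = x.reshape((c, d // factor, factor, h // factor, factor,
                                w // factor, factor))
            return blocks.mean(axis=(2, 4, 6))
        return resize_field(x, lvl_shape)

    for i in range(1, 5):
        lvl_shape = tuple(s // 2**i for s in shape)
        f_i = down(f.reshape((1,) + shape), 2**i, lvl_shape)
        m_i = down(m.reshape((1,) + shape), 2**i, lvl_shape)
        sim = lncc_loss(f_i, warp(m_i, grids[i]), cfg)
        breakdown[f"sim_level_{i}"] = sim.item()
        total = sim if total is None else total + sim
    smooth = smoothness_loss(
        aggregate if isinstance(aggregate, Tensor) else Tensor(np.asarray(aggregate)))
    smooth_w = ad.mul(smooth, cfg.lam)
    breakdown["smooth"] = smooth_w.item()
    total = total + smooth_w
    breakdown["total"] = total.item()
    return total, breakdown
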