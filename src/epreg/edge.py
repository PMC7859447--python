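"""3D Sobel edge maps used as the second input channel of each stream.

The edge map is the Euclidean norm of the three directional gradient
responses of a 3x3x3 Sobel operator.  Because the norm is invariant under
kernel flipping, the operator is applied as a cross-correlation; borders are
handled by edge replication so the output keeps the input shape and border
gradients are not artificially inflated.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["sobel_kernels", "sobel_edge_map", "make_dual_input"]


def sobel_kernels() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three 3x3x3 Sobel kernels ``(S_0, S_1, S_2)``.

    ``S_a`` differentiates along array axis ``a``: its slice at offset -1
    along that axis is the smoothing stencil ``[[1,2,1],[2,4,2],[1,2,1]]``,
    the central slice is zero, and the +1 slice is the negation.
    """
    smooth = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=np.int64)
    kernels = []
    for axis in range(3):
        k = np.zeros((3, 3, 3), dtype=np.int64)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = 0
        sl_hi[axis] = 2
        k[tuple(sl_lo)] = smooth
        k[tuple(sl_hi)] = -smooth
        kernels.append(k)
    return tuple(kernels)


def sobel_edge_map(volume: np.ndarray) -> np.ndarray:
    """Edge magnitude ``sqrt(sum_a (S_a * I)^2)`` with replicate borders."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {volume.ndim}D")
    if min(volume.shape) < 3:
        raise ValueError(
            f"every axis must be >= 3 for a 3x3x3 operator, got {volume.shape}")
    acc = np.zeros_like(volume)
    for k in sobel_kernels():
        resp = ndimage.correlate(volume, k.astype(np.float64), mode="nearest")
        acc += resp**2
    return np.sqrt(acc)


def make_dual_input(volume: np.ndarray, edge: np.ndarray | None = None
                    ) -> np.ndarray:
    """Stack intensity and rescaled edge map into a 2-channel input.

    Channel 0 is the (already [0,1]-normalized) intensity volume; channel 1
    is the edge map rescaled to [0,1] so both channels enter the encoder on
    comparable scales.  A constant volume has a zero edge channel.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if edge is None:
        edge = sobel_edge_map(volume)
    edge = np.asarray(edge, dtype=np.float64)
    if edge.shape != volume.shape:
        raise ValueError(
            f"edge map shape {edge.shape} != volume shape {volume.shape}")
    emax = edge.max()
    scaled = edge / emax if emax > 0 else np.zeros_like(edge)
    return np.stack([volume, scaled], axis=0)
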