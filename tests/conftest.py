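import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent brute-force oracles (triple loops; no shared code with epreg)
# ---------------------------------------------------------------------------

def brute_correlate(volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct 3x3x3 cross-correlation with replicate padding."""
    out = np.zeros_like(volume, dtype=np.float64)
    d, h, w = volume.shape
    for i in range(d):
        for j in range(h):
            for k in range(w):
                acc = 0.0
                for a in (-1, 0, 1):
                    for b in (-1, 0, 1):
                        for c in (-1, 0, 1):
                            ii = min(max(i + a, 0), d - 1)
                            jj = min(max(j + b, 0), h - 1)
                            kk = min(max(k + c, 0), w - 1)
                            acc += kernel[a + 1, b + 1, c + 1] * volume[ii, jj, kk]
                out[i, j, k] = acc
    return out


def brute_trilinear(volume: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Per-voxel trilinear interpolation at normalized align-corners coords,
    clamping out-of-domain samples to the border."""
    dims = volume.shape
    out_sp = grid.shape[1:]
    out = np.zeros(out_sp, dtype=np.float64)
    for i in range(out_sp[0]):
        for j in range(out_sp[1]):
            for k in range(out_sp[2]):
                pos = []
                for ax, idx in enumerate((i, j, k)):
                    n = dims[ax]
                    p = (grid[ax, i, j, k] + 1.0) * 0.5 * (n - 1)
                    pos.append(min(max(p, 0.0), n - 1))
                i0 = [int(np.floor(p)) for p in pos]
                i1 = [min(a + 1, dims[ax] - 1) for ax, a in enumerate(i0)]
                t = [pos[ax] - i0[ax] for ax in range(3)]
                acc = 0.0
                for ca in (0, 1):
                    for cb in (0, 1):
                        for cc in (0, 1):
                            wgt = ((t[0] if ca else 1 - t[0])
                                   * (t[1] if cb else 1 - t[1])
                                   * (t[2] if cc else 1 - t[2]))
                            acc += wgt * volume[(i1[0] if ca else i0[0]),
                                                (i1[1] if cb else i0[1]),
                                                (i1[2] if cc else i0[2])]
                out[i, j, k] = acc
    return out


def brute_lncc(fixed: np.ndarray, warped: np.ndarray, v: int,
               eps: float = 1e-5) -> float:
    """Direct per-voxel windowed NCC sum with replicate padding."""
    r = v // 2
    fp = np.pad(fixed, r, mode="edge")
    wp = np.pad(warped, r, mode="edge")
    total = 0.0
    d, h, w = fixed.shape
    for i in range(d):
        for j in range(h):
            for k in range(w):
                pf = fp[i:i + v, j:j + v, k:k + v]
                pw = wp[i:i + v, j:j + v, k:k + v]
                cf = pf - pf.mean()
                cw = pw - pw.mean()
                cross = (cf * cw).sum()
                total += cross**2 / ((cf**2).sum() * (cw**2).sum() + eps)
    return -total
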