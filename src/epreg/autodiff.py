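"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides the differentiable primitives the registration network
needs — elementwise arithmetic, matrix multiply, 3D convolution, trilinear
grid sampling, sliding box sums — as a small tape-based engine.  It is not a
general deep-learning framework: only the operations used by the network and
its losses are implemented, each with an analytically derived adjoint that is
exercised by finite-difference gradient checks in the test suite.

Conventions
-----------
* Feature grids are ``(C, D, H, W)`` arrays (channel-first, no batch axis;
  the trainer operates on one volume pair at a time).
* Sampling grids and displacement fields are ``(3, D, H, W)`` with component
  ``c`` addressing array axis ``c`` in normalized ``[-1, 1]`` coordinates
  under the align-corners convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "astensor",
    "concat",
    "conv3d",
    "grid_sample",
    "box_sum3d",
    "relu",
]


class Tensor:
    """A numpy array with an optional gradient tape behind it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- factory -----------------------------------------------------------
    @staticmethod
    def _from_op(data, parents, backward):
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        """Reverse-accumulate gradients from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs get deep at fine pyramid levels
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(other, mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------------

def _coerce_pair(a, b):
    """Wrap operands, keeping python scalars in the partner's dtype so a
    float32 graph is not silently promoted to float64."""
    if isinstance(a, Tensor) and not isinstance(b, Tensor) and np.isscalar(b):
        return a, Tensor(np.asarray(b, dtype=a.data.dtype))
    if isinstance(b, Tensor) and not isinstance(a, Tensor) and np.isscalar(a):
        return Tensor(np.asarray(a, dtype=b.data.dtype)), b
    return astensor(a), astensor(b)


def add(a, b) -> Tensor:
    a, b = _coerce_pair(a, b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor._from_op(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _coerce_pair(a, b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor._from_op(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _coerce_pair(a, b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / b.data**2, b.shape))

    return Tensor._from_op(out_data, (a, b), backward)


def square(a) -> Tensor:
    return mul(a, a)


def sqrt(a) -> Tensor:
    a = astensor(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * 0.5 / np.maximum(out_data, 1e-300))

    return Tensor._from_op(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor._from_op(a.data * mask, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor._from_op(out_data, (a, b), backward)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

    return Tensor._from_op(out_data, (a,), backward)


def mean_(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return Tensor._from_op(out_data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[idx] = g  # basic (slice) indexing only: no repeats
            a._accumulate(full)

    return Tensor._from_op(out_data, (a,), backward)


def concat(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# 3D convolution (channel-first, single sample)
# ---------------------------------------------------------------------------

def _conv3d_raw(x: np.ndarray, w: np.ndarray, stride: int, dilation: int,
                pad: int) -> np.ndarray:
    """Plain strided/dilated cross-correlation of (Cin,D,H,W) with
    (Cout,Cin,k,k,k), zero padding ``pad`` on every spatial side."""
    cout, cin, k, _, _ = w.shape
    xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3)
    ke = (k - 1) * dilation + 1
    do, ho, wo = ((xp.shape[1] - ke) // stride + 1,
                  (xp.shape[2] - ke) // stride + 1,
                  (xp.shape[3] - ke) // stride + 1)
    # gather columns one kernel offset at a time: each copy is a simple
    # 4D strided slice, far cheaper than materializing the 7D window view
    cols = np.empty((cin, k, k, k, do, ho, wo), dtype=xp.dtype)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                oa, ob, oc = a * dilation, b * dilation, c * dilation
                cols[:, a, b, c] = xp[:, oa:oa + (do - 1) * stride + 1:stride,
                                      ob:ob + (ho - 1) * stride + 1:stride,
                                      oc:oc + (wo - 1) * stride + 1:stride]
    cols = cols.reshape(cin * k**3, do * ho * wo)
    y = w.reshape(cout, cin * k**3) @ cols
    return y.reshape(cout, do, ho, wo), cols


def conv3d(x, w, b=None, stride: int = 1, dilation: int = 1,
           padding: int | None = None) -> Tensor:
    """3D cross-correlation with zero padding.

    ``padding=None`` means 'same' for the given dilation (k odd), so an input
    with even axes and stride 2 halves exactly.
    """
    x, w = astensor(x), astensor(w)
    cout, cin, k, _, _ = w.shape
    if padding is None:
        padding = dilation * (k // 2)
    y, cols = _conv3d_raw(x.data, w.data, stride, dilation, padding)
    parents = [x, w]
    if b is not None:
        b = astensor(b)
        y = y + b.data.reshape(cout, 1, 1, 1)
        parents.append(b)
    n_in = x.shape[1:]

    def backward(g):
        g = g.astype(w.dtype, copy=False)  # keep heavy math in op precision
        gm = g.reshape(cout, -1)
        if b is not None and b.requires_grad:
            b._accumulate(gm.sum(axis=1))
        if w.requires_grad:
            gw = gm @ cols.T
            w._accumulate(gw.reshape(w.shape))
        if x.requires_grad:
            # transposed convolution: zero-stuff stride, flip kernel,
            # swap in/out channels, full-pad, then stride-1 correlate.
            ke = (k - 1) * dilation + 1
            do, ho, wo = g.shape[1:]
            ds, hs, ws = ((do - 1) * stride + 1, (ho - 1) * stride + 1,
                          (wo - 1) * stride + 1)
            gu = np.zeros((cout, ds, hs, ws), dtype=g.dtype)
            gu[:, ::stride, ::stride, ::stride] = g
            lo = ke - 1 - padding
            # high-side pad so the output covers the whole input extent
            hi = [n_in[i] - (ds, hs, ws)[i] + padding for i in range(3)]
            gp = np.pad(gu, ((0, 0), (lo, hi[0]), (lo, hi[1]), (lo, hi[2])))
            wf = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
            gx, _ = _conv3d_raw(gp, wf, 1, dilation, 0)
            x._accumulate(gx)

    return Tensor._from_op(y, tuple(parents), backward)


# ---------------------------------------------------------------------------
# trilinear grid sampling (align-corners, border clamping)
# ---------------------------------------------------------------------------

def grid_sample(x, grid) -> Tensor:
    """Sample ``x`` (C,D,H,W) at ``grid`` (3,d,h,w) normalized coordinates.

    Align-corners semantics: coordinate -1 maps to index 0 and +1 to index
    n-1 along each axis.  Out-of-domain samples clamp to the border value.
    Differentiable in both the image and the grid.
    """
    x, grid = astensor(x), astensor(grid)
    if grid.shape[0] != 3:
        raise ValueError("grid must have 3 coordinate components first")
    if not np.all(np.isfinite(grid.data)):
        raise FloatingPointError("non-finite sampling grid")
    C = x.shape[0]
    dims = x.shape[1:]
    out_sp = grid.shape[1:]

    pos, i0, i1, frac, inside = [], [], [], [], []
    for ax in range(3):
        n = dims[ax]
        p = (grid.data[ax] + 1.0) * 0.5 * (n - 1)
        ins = (p > 0.0) & (p < n - 1)  # clamped coords have zero grid-grad
        p = np.clip(p, 0.0, n - 1)
        f0 = np.floor(p)
        a0 = f0.astype(np.intp)
        a1 = np.minimum(a0 + 1, n - 1)
        pos.append(p)
        i0.append(a0)
        i1.append(a1)
        frac.append(p - f0)
        inside.append(ins)

    t0, t1, t2 = frac
    corners = {}
    out = np.zeros((C,) + out_sp, dtype=x.dtype)
    weights = {}
    for c0 in (0, 1):
        for c1 in (0, 1):
            for c2 in (0, 1):
                idx = ((i1[0] if c0 else i0[0]),
                       (i1[1] if c1 else i0[1]),
                       (i1[2] if c2 else i0[2]))
                v = x.data[:, idx[0], idx[1], idx[2]]
                wgt = ((t0 if c0 else 1 - t0)
                       * (t1 if c1 else 1 - t1)
                       * (t2 if c2 else 1 - t2))
                out += v * wgt[None]
                corners[(c0, c1, c2)] = (idx, v)
                weights[(c0, c1, c2)] = wgt

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gc = g.astype(x.dtype, copy=False)
            for key, (idx, _v) in corners.items():
                contrib = gc * weights[key][None]
                flat = (idx[0] * dims[1] + idx[1]) * dims[2] + idx[2]
                gx2 = gx.reshape(C, -1)
                np.add.at(gx2, (slice(None), flat.ravel()),
                          contrib.reshape(C, -1))
            x._accumulate(gx)
        if grid.requires_grad:
            gg = np.zeros_like(grid.data)
            axes_t = [t0, t1, t2]
            for ax in range(3):
                dpos = np.zeros(out_sp, dtype=np.float64)
                for key, (idx, v) in corners.items():
                    sign = 1.0 if key[ax] == 1 else -1.0
                    wgt = np.ones(out_sp, dtype=np.float64)
                    for other in range(3):
                        if other == ax:
                            continue
                        t = axes_t[other]
                        wgt = wgt * (t if key[other] == 1 else 1 - t)
                    dpos += sign * (g * v).sum(axis=0) * wgt
                scale = 0.5 * (dims[ax] - 1)
                gg[ax] = dpos * scale * inside[ax]
            grid._accumulate(gg)

    return Tensor._from_op(out, (x, grid), backward)


# ---------------------------------------------------------------------------
# separable trilinear resize (axis-aligned special case of grid sampling)
# ---------------------------------------------------------------------------

def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Align-corners 1D linear interpolation matrix (n_out x n_in)."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    if n_out == 1:
        m[0, 0] = 1.0  # coordinate 0 of a singleton axis maps to index 0
        return m
    src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    i0 = np.minimum(np.floor(src).astype(int), n_in - 2)
    t = src - i0
    m[np.arange(n_out), i0] = 1 - t
    m[np.arange(n_out), i0 + 1] = t
    return m


def resize3d(x, out_shape: tuple[int, int, int]) -> Tensor:
    """Trilinear resize of a (C, D, H, W) grid to ``out_shape``.

    Mathematically identical to align-corners grid sampling on the identity
    grid of the target shape, but computed separably per axis.
    """
    x = astensor(x)
    mats = [_resize_matrix(x.shape[1 + ax], out_shape[ax]).astype(x.dtype)
            for ax in range(3)]
    y = x.data
    for ax, m in enumerate(mats):
        y = np.moveaxis(np.tensordot(m, y, axes=(1, 1 + ax)), 0, 1 + ax)

    def backward(g):
        if not x.requires_grad:
            return
        for ax, m in enumerate(mats):
            g = np.moveaxis(np.tensordot(m.T, g, axes=(1, 1 + ax)), 0, 1 + ax)
        x._accumulate(g)

    return Tensor._from_op(y, (x,), backward)


# ---------------------------------------------------------------------------
# sliding box sums (for windowed cross-correlation)
# ---------------------------------------------------------------------------

def _box1d_valid(x: np.ndarray, v: int, axis: int) -> np.ndarray:
    x = np.moveaxis(x, axis, -1)
    cs = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,), dtype=x.dtype), np.cumsum(x, axis=-1)],
        axis=-1)
    y = cs[..., v:] - cs[..., :-v]
    return np.moveaxis(y, -1, axis)


def _box1d_full(g: np.ndarray, v: int, axis: int) -> np.ndarray:
    """Adjoint of the valid box sum: full correlation with a ones kernel."""
    g = np.moveaxis(g, axis, -1)
    padded = np.pad(g, [(0, 0)] * (g.ndim - 1) + [(v - 1, v - 1)])
    cs = np.concatenate(
        [np.zeros(padded.shape[:-1] + (1,), dtype=g.dtype),
         np.cumsum(padded, axis=-1)], axis=-1)
    y = cs[..., v:] - cs[..., :-v]
    return np.moveaxis(y, -1, axis)


def _pad_replicate_adjoint(g: np.ndarray, r: int, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    core = g[..., r:g.shape[-1] - r].copy()
    core[..., 0] += g[..., :r].sum(axis=-1)
    core[..., -1] += g[..., g.shape[-1] - r:].sum(axis=-1)
    return np.moveaxis(core, -1, axis)


def box_sum3d(x, v: int) -> Tensor:
    """Same-shape sliding v³ window sum with edge-replicate padding."""
    if v % 2 == 0 or v < 1:
        raise ValueError("window size must be odd and positive")
    x = astensor(x)
    r = v // 2
    y = x.data
    spatial = tuple(range(y.ndim - 3, y.ndim))
    for ax in spatial:
        pad = [(0, 0)] * y.ndim
        pad[ax] = (r, r)
        y = np.pad(y, pad, mode="edge")
        y = _box1d_valid(y, v, ax)

    def backward(g):
        if not x.requires_grad:
            return
        gx = g
        for ax in reversed(spatial):
            gx = _box1d_full(gx, v, ax)
            gx = _pad_replicate_adjoint(gx, r, ax)
        x._accumulate(gx)

    return Tensor._from_op(y, (x,), backward)
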