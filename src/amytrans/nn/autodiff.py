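"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the primitives the deformable-convolution U-Net
needs: broadcast-aware arithmetic, reductions, reshaping, 2D (transposed and
depthwise) convolution in NHWC layout, GELU/softmax, and an indexed gather
used by bilinear sampling. Gradients are accumulated by a topological sweep
over the tape; graphs are rebuilt every forward pass.

Layout convention: feature maps are channels-last, ``(N, H, W, C)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "const"]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float64)
        self.data = data
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        # iterative topological sort (graphs can exceed the recursion limit)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free tape memory as we go
                node._backward = None
                node._parents = ()

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_(self, p)


def const(x, dtype=None) -> Tensor:
    arr = np.asarray(x, dtype=dtype)
    return Tensor(arr)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _acc(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    g = _unbroadcast(g, t.data.shape)
    t.grad = g if t.grad is None else t.grad + g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _acc(a, g)
        _acc(b, g)

    return _make(a.data + b.data, (a, b), bw)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _acc(a, g)
        _acc(b, -g)

    return _make(a.data - b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _acc(a, g * b.data)
        _acc(b, g * a.data)

    return _make(a.data * b.data, (a, b), bw)


def div(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _acc(a, g / b.data)
        _acc(b, -g * a.data / (b.data * b.data))

    return _make(a.data / b.data, (a, b), bw)


def neg(a: Tensor) -> Tensor:
    def bw(g):
        _acc(a, -g)

    return _make(-a.data, (a,), bw)


def pow_(a: Tensor, p: float) -> Tensor:
    def bw(g):
        _acc(a, g * p * a.data ** (p - 1.0))

    return _make(a.data ** p, (a,), bw)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bw(g):
        _acc(a, g * out_data)

    return _make(out_data, (a,), bw)


def sqrt(a: Tensor) -> Tensor:
    out_data = np.sqrt(a.data)

    def bw(g):
        _acc(a, g * 0.5 / out_data)

    return _make(out_data, (a,), bw)


def abs_(a: Tensor) -> Tensor:
    def bw(g):
        _acc(a, g * np.sign(a.data))

    return _make(np.abs(a.data), (a,), bw)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def bw(g):
        if axis is None:
            _acc(a, np.broadcast_to(g, a.data.shape))
        else:
            gk = g if keepdims else np.expand_dims(g, axis)
            _acc(a, np.broadcast_to(gk, a.data.shape))

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), Tensor(np.asarray(1.0 / n, dtype=a.dtype)))


def reshape(a: Tensor, shape) -> Tensor:
    def bw(g):
        _acc(a, g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), bw)


def transpose_(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def bw(g):
        _acc(a, g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), bw)


def concat(tensors, axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _acc(t, g[tuple(idx)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def bw(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        _acc(a, full)

    return _make(a.data[idx], (a,), bw)


def pad_hw(a: Tensor, pt: int, pb: int, pl: int, pr: int) -> Tensor:
    """Zero-pad the H and W axes of an (N, H, W, C) tensor."""

    def bw(g):
        H, W = a.data.shape[1], a.data.shape[2]
        _acc(a, g[:, pt:pt + H, pl:pl + W, :])

    padded = np.pad(a.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    return _make(padded, (a,), bw)


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def gelu(a: Tensor) -> Tensor:
    x = a.data
    # erf may upcast float32; keep the graph dtype-stable
    cdf = (0.5 * (1.0 + erf(x * _INV_SQRT2))).astype(x.dtype, copy=False)

    def bw(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        _acc(a, (g * (cdf + x * pdf)).astype(x.dtype, copy=False))

    return _make(x * cdf, (a,), bw)


def softmax_last(a: Tensor) -> Tensor:
    z = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        _acc(a, y * (g - dot))

    return _make(y, (a,), bw)


# ---------------------------------------------------------------------------
# linear / convolution
# ---------------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``y = x @ w (+ b)`` over the last axis; x is (..., Cin), w is (Cin, Cout)."""
    out_data = x.data @ w.data
    if b is not None:
        out_data = out_data + b.data

    def bw(g):
        g2 = g.reshape(-1, g.shape[-1])
        x2 = x.data.reshape(-1, x.data.shape[-1])
        _acc(w, x2.T @ g2)
        if b is not None:
            _acc(b, g2.sum(axis=0))
        _acc(x, g @ w.data.T)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int = 0) -> Tensor:
    """2D cross-correlation, NHWC input, weight ``(kh, kw, Cin, Cout)``."""
    kh, kw, cin, cout = w.data.shape
    s = stride
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x.data
    # im2col + BLAS (substantially faster than einsum on these shapes)
    win = np.ascontiguousarray(
        sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::s, ::s])
    N, Ho, Wo = win.shape[:3]
    w2 = w.data.transpose(2, 0, 1, 3).reshape(cin * kh * kw, cout)
    out_data = win.reshape(N, Ho, Wo, cin * kh * kw) @ w2
    if b is not None:
        out_data = out_data + b.data

    def bw(g):
        wf = win.reshape(-1, cin * kh * kw)
        gf = g.reshape(-1, cout)
        _acc(w, (wf.T @ gf).reshape(cin, kh, kw, cout).transpose(1, 2, 0, 3))
        if b is not None:
            _acc(b, gf.sum(axis=0))
        if x.requires_grad:
            Ho, Wo = g.shape[1], g.shape[2]
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i:i + s * (Ho - 1) + 1:s, j:j + s * (Wo - 1) + 1:s, :] += (
                        g @ w.data[i, j].T)
            H, W = x.data.shape[1], x.data.shape[2]
            _acc(x, gxp[:, pad:pad + H, pad:pad + W, :] if pad else gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bw)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with a 2x2 kernel, stride 2 (exact 2x upsampling).

    Weight shape ``(2, 2, Cin, Cout)``; output is (N, 2H, 2W, Cout).
    """
    N, H, W, cin = x.data.shape
    cout = w.data.shape[-1]
    out_data = np.empty((N, 2 * H, 2 * W, cout), dtype=x.data.dtype)
    for i in range(2):
        for j in range(2):
            out_data[:, i::2, j::2, :] = x.data @ w.data[i, j]
    if b is not None:
        out_data = out_data + b.data

    def bw(g):
        if b is not None:
            _acc(b, g.sum(axis=(0, 1, 2)))
        gx = np.zeros_like(x.data)
        for i in range(2):
            for j in range(2):
                gx += g[:, i::2, j::2, :] @ w.data[i, j].T
        _acc(x, gx)
        gw = np.empty_like(w.data)
        x2 = x.data.reshape(-1, cin)
        for i in range(2):
            for j in range(2):
                gw[i, j] = x2.T @ g[:, i::2, j::2, :].reshape(-1, cout)
        _acc(w, gw)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bw)


def depthwise3x3(x: Tensor, w: Tensor) -> Tensor:
    """Depthwise 3x3 convolution, stride 1, zero pad 1; weight ``(3, 3, C)``."""
    N, H, W, C = x.data.shape
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,C,3,3)
    out_data = np.einsum("nhwckl,klc->nhwc", win, w.data, optimize=True)

    def bw(g):
        _acc(w, np.einsum("nhwckl,nhwc->klc", win, g, optimize=True))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(3):
                for j in range(3):
                    gxp[:, i:i + H, j:j + W, :] += g * w.data[i, j]
            _acc(x, gxp[:, 1:1 + H, 1:1 + W, :])

    return _make(out_data, (x, w), bw)


def weighted_sum_k(samp: Tensor, wgt: Tensor) -> Tensor:
    """Contract the K axis: ``out[..., c] = sum_k samp[..., k, c] * wgt[..., k]``.

    ``samp`` is (..., K, C), ``wgt`` is (..., K). Fused einsum primitive used
    by deformable sampling (cheaper than broadcast-multiply-then-sum).
    """
    out_data = (wgt.data[..., None, :] @ samp.data)[..., 0, :]

    def bw(g):
        _acc(samp, wgt.data[..., :, None] @ g[..., None, :])
        _acc(wgt, (samp.data @ g[..., :, None])[..., 0])

    return _make(out_data, (samp, wgt), bw)


def deform_sample(value: Tensor, py: Tensor, px: Tensor, mod: Tensor) -> Tensor:
    """Fused modulated bilinear sampling (numba kernel) with analytic adjoint.

    ``value`` is (N, H, W, G, Cp); ``py``/``px``/``mod`` are (N, H, W, G, K).
    Returns the modulation-weighted sum over taps, (N, H, W, G, Cp).
    Gradients flow to the feature map, the sampling coordinates and the
    modulation weights.
    """
    from ._deform import deform_sample_bwd, deform_sample_fwd

    out_data = np.empty_like(value.data)
    deform_sample_fwd(value.data, py.data, px.data, mod.data, out_data)

    def bw(g):
        gvalue = np.zeros_like(value.data)
        gpy = np.empty_like(py.data)
        gpx = np.empty_like(px.data)
        gmod = np.empty_like(mod.data)
        deform_sample_bwd(value.data, py.data, px.data, mod.data,
                          np.ascontiguousarray(g), gvalue, gpy, gpx, gmod)
        _acc(value, gvalue)
        _acc(py, gpy)
        _acc(px, gpx)
        _acc(mod, gmod)

    return _make(out_data, (value, py, px, mod), bw)


def gather_hw(x: Tensor, iy: np.ndarray, ix: np.ndarray) -> Tensor:
    """Group-wise spatial gather used by deformable sampling.

    ``x`` is (N, H, W, G, Cp); ``iy``/``ix`` are integer index arrays of shape
    (N, P, G, K) with values assumed already clipped into range. Returns
    (N, P, G, K, Cp) where ``out[n,p,g,k] = x[n, iy[n,p,g,k], ix[n,p,g,k], g]``.
    """
    N, H, W, G, Cp = x.data.shape
    n_idx = np.arange(N)[:, None, None, None]
    g_idx = np.arange(G)[None, None, :, None]
    out_data = x.data[n_idx, iy, ix, g_idx]

    def bw(g):
        # scatter-add via bincount (much faster than np.add.at)
        flat = (((n_idx * H + iy) * W + ix) * G + g_idx).ravel()
        nbins = N * H * W * G
        gx = np.empty((nbins, Cp), dtype=x.data.dtype)
        g2 = g.reshape(-1, Cp)
        for c in range(Cp):
            gx[:, c] = np.bincount(flat, weights=g2[:, c], minlength=nbins)
        _acc(x, gx.reshape(x.data.shape))

    return _make(out_data, (x,), bw)
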