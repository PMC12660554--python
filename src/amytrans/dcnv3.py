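"""Deformable convolution v3 (DCNv3) operator and basic block.

A DCNv3 layer replaces the fixed square sampling grid of an ordinary
convolution with per-location, per-group *learned* fractional offsets and
softmax-normalized modulation weights:

    out_g(p) = W_out [ sum_k m_k(p) * V_g(p + grid_k + dp_k(p)) ]

where ``V = W_in x`` is a pointwise input projection split into ``G`` channel
groups of ``C'`` channels, ``grid_k`` enumerates the K = kernel^2 taps of the
nominal grid, and the offsets ``dp_k`` and modulations ``m_k`` are predicted
from the input by a depthwise 3x3 convolution followed by pointwise linear
maps. Sampling at fractional positions is bilinear with a zero-padding
convention (positions outside the map contribute 0).

Offsets and modulation logits are zero-initialized, so an untrained layer is
a plain k x k box smoother — a useful closed-form reduction exercised by the
test-suite, alongside a loop-based naive oracle (`dcnv3_forward_naive`).
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

from .nn import autodiff as ad
from .nn import Linear, LayerNorm, Module, Tensor


def kernel_grid(kernel: int) -> np.ndarray:
    """Nominal sampling grid, row-major (dy, dx) pairs, shape (K, 2)."""
    r = kernel // 2
    return np.array([(i - r, j - r) for i in range(kernel) for j in range(kernel)],
                    dtype=np.float64)


def bilinear_sample(feature: np.ndarray, y: float, x: float, channel: int = 0) -> float:
    """Bilinearly interpolate ``feature`` at fractional position (y, x).

    ``feature`` is (H, W) or (C, H, W); locations outside [0, H-1] x [0, W-1]
    contribute zero (zero-padding convention).
    """
    arr = feature if feature.ndim == 2 else feature[channel]
    H, W = arr.shape
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    fy, fx = y - y0, x - x0
    val = 0.0
    for dy, wy in ((0, 1.0 - fy), (1, fy)):
        for dx, wx in ((0, 1.0 - fx), (1, fx)):
            yy, xx = y0 + dy, x0 + dx
            if 0 <= yy < H and 0 <= xx < W:
                val += wy * wx * arr[yy, xx]
    return float(val)


class DCNv3(Module):
    """The deformable-convolution operator (channels-last, NHWC)."""

    def __init__(self, channels: int, groups: int, rng: np.random.Generator,
                 kernel: int = 3, dtype=np.float32, fused: bool = True):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd")
        from .nn._deform import HAVE_NUMBA
        self.fused = bool(fused) and HAVE_NUMBA
        if channels % groups != 0:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.channels = channels
        self.groups = groups
        self.kernel = kernel
        self.K = kernel * kernel
        self.group_dim = channels // groups
        self.dtype = dtype

        self.in_proj = Linear(channels, channels, rng, dtype)
        self.dw = Tensor(
            (rng.standard_normal((3, 3, channels)) * np.sqrt(1.0 / 9.0)).astype(dtype),
            requires_grad=True)
        self.dw_norm = LayerNorm(channels, dtype)
        # zero-init: the untrained operator starts as a uniform box smoother
        self.offset = Linear(channels, groups * self.K * 2, rng, dtype, zero_init=True)
        self.mask = Linear(channels, groups * self.K, rng, dtype, zero_init=True)
        self.out_proj = Linear(channels, channels, rng, dtype)

        grid = kernel_grid(kernel)
        self._grid_dy = grid[:, 0]
        self._grid_dx = grid[:, 1]

    def predict_offsets(self, x: Tensor):
        """Offsets (N,H,W,G,K,2) and normalized modulation (N,H,W,G,K)."""
        N, H, W, C = x.shape
        G, K = self.groups, self.K
        feat = ad.gelu(self.dw_norm(ad.depthwise3x3(x, self.dw)))
        off = ad.reshape(self.offset(feat), (N, H, W, G, K, 2))
        mod = ad.softmax_last(ad.reshape(self.mask(feat), (N, H, W, G, K)))
        return off, mod

    def forward(self, x: Tensor) -> Tensor:
        N, H, W, C = x.shape
        G, Cp, K = self.groups, self.group_dim, self.K
        dt = x.dtype

        value = ad.reshape(self.in_proj(x), (N, H, W, G, Cp))
        off, mod = self.predict_offsets(x)

        base_y = (np.arange(H, dtype=dt)[:, None] + self._grid_dy[None, :]).astype(dt)
        base_x = (np.arange(W, dtype=dt)[:, None] + self._grid_dx[None, :]).astype(dt)
        py = ad.add(ad.reshape(ad.narrow(off, 5, 0, 1), (N, H, W, G, K)),
                    ad.const(base_y.reshape(1, H, 1, 1, K)))
        px = ad.add(ad.reshape(ad.narrow(off, 5, 1, 1), (N, H, W, G, K)),
                    ad.const(base_x.reshape(1, 1, W, 1, K)))

        out = self._bilinear(value, py, px, mod, H, W)
        return self.out_proj(ad.reshape(out, (N, H, W, C)))

    def _bilinear(self, value: Tensor, py: Tensor, px: Tensor, mod: Tensor,
                  H: int, W: int) -> Tensor:
        """Differentiable zero-padded bilinear sampling with modulation.

        Returns the modulation-weighted aggregate over the K kernel taps,
        shape (N, H, W, G, Cp). Corner contributions are contracted over K
        with a fused einsum so the (K x Cp)-sized broadcast never materializes
        through slow paths.
        """
        N = value.shape[0]
        G, Cp, K = self.groups, self.group_dim, self.K
        dt = value.dtype
        if self.fused:
            return ad.deform_sample(value, py, px, mod)
        y0 = np.floor(py.data)
        x0 = np.floor(px.data)
        fy = ad.sub(py, ad.const(y0.astype(dt)))
        fx = ad.sub(px, ad.const(x0.astype(dt)))
        one = ad.const(np.asarray(1.0, dtype=dt))
        wy = (ad.sub(one, fy), fy)
        wx = (ad.sub(one, fx), fx)

        acc = None
        for dy in (0, 1):
            yc = y0 + dy
            for dx in (0, 1):
                xc = x0 + dx
                valid = ((yc >= 0) & (yc <= H - 1) & (xc >= 0) & (xc <= W - 1))
                iy = np.clip(yc, 0, H - 1).astype(np.intp).reshape(N, -1, G, K)
                ix = np.clip(xc, 0, W - 1).astype(np.intp).reshape(N, -1, G, K)
                samp = ad.reshape(ad.gather_hw(value, iy, ix),
                                  (N, py.shape[1], py.shape[2], G, K, Cp))
                wgt = ad.mul(ad.mul(ad.mul(wy[dy], wx[dx]),
                                    ad.const(valid.astype(dt))), mod)
                term = ad.weighted_sum_k(samp, wgt)
                acc = term if acc is None else ad.add(acc, term)
        return acc


def _layernorm_np(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                  eps: float = 1e-6) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def _gelu_np(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def dcnv3_forward_naive(layer: DCNv3, x: np.ndarray) -> np.ndarray:
    """Loop-based oracle for :meth:`DCNv3.forward` (forward only).

    Explicit loops over batch, location, group and kernel tap; no
    vectorization. Used to verify the fast path.
    """
    x = np.asarray(x, dtype=np.float64)
    N, H, W, C = x.shape
    G, Cp, K = layer.groups, layer.group_dim, layer.K
    w_in, b_in = layer.in_proj.w.data.astype(np.float64), layer.in_proj.b.data.astype(np.float64)
    w_out, b_out = layer.out_proj.w.data.astype(np.float64), layer.out_proj.b.data.astype(np.float64)

    value = x @ w_in + b_in

    # offset/mask predictor: depthwise 3x3 -> LN -> GELU -> pointwise
    dw = layer.dw.data.astype(np.float64)
    feat = np.zeros_like(x)
    for n in range(N):
        for h in range(H):
            for w in range(W):
                for c in range(C):
                    s = 0.0
                    for i in range(3):
                        for j in range(3):
                            hh, ww = h + i - 1, w + j - 1
                            if 0 <= hh < H and 0 <= ww < W:
                                s += x[n, hh, ww, c] * dw[i, j, c]
                    feat[n, h, w, c] = s
    feat = _gelu_np(_layernorm_np(feat, layer.dw_norm.gamma.data.astype(np.float64),
                                  layer.dw_norm.beta.data.astype(np.float64)))
    off = (feat @ layer.offset.w.data.astype(np.float64)
           + layer.offset.b.data.astype(np.float64)).reshape(N, H, W, G, K, 2)
    logits = (feat @ layer.mask.w.data.astype(np.float64)
              + layer.mask.b.data.astype(np.float64)).reshape(N, H, W, G, K)

    grid = kernel_grid(layer.kernel)
    out = np.zeros((N, H, W, C))
    vol = value.reshape(N, H, W, G, Cp)
    for n in range(N):
        for h in range(H):
            for w in range(W):
                for g in range(G):
                    z = logits[n, h, w, g]
                    e = np.exp(z - z.max())
                    m = e / e.sum()
                    acc = np.zeros(Cp)
                    for k in range(K):
                        yy = h + grid[k, 0] + off[n, h, w, g, k, 0]
                        xx = w + grid[k, 1] + off[n, h, w, g, k, 1]
                        for c in range(Cp):
                            acc[c] += m[k] * bilinear_sample(vol[n, :, :, g, c], yy, xx)
                    out[n, h, w, g * Cp:(g + 1) * Cp] = acc
    return out @ w_out + b_out


class FFN(Module):
    """Two pointwise linear maps with a GELU in between."""

    def __init__(self, channels: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.fc1 = Linear(channels, hidden, rng, dtype)
        self.fc2 = Linear(hidden, channels, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(ad.gelu(self.fc1(x)))


class DCNv3Block(Module):
    """Pre-norm residual block: x + DCNv3(LN(x)), then y + FFN(LN(y))."""

    def __init__(self, channels: int, groups: int, rng: np.random.Generator,
                 kernel: int = 3, ffn_ratio: int = 4, dtype=np.float32):
        super().__init__()
        self.norm1 = LayerNorm(channels, dtype)
        self.dcn = DCNv3(channels, groups, rng, kernel, dtype)
        self.norm2 = LayerNorm(channels, dtype)
        self.ffn = FFN(channels, ffn_ratio * channels, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        y = ad.add(x, self.dcn(self.norm1(x)))
        return ad.add(y, self.ffn(self.norm2(y)))
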