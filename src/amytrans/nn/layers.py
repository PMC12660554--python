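"""Lightweight neural-network modules over the autodiff engine.

Modules register parameters and child modules via attribute assignment, so
``named_parameters`` yields a deterministic, insertion-ordered flat view that
the optimizer and the checkpoint format both rely on.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        mine = dict(self.named_parameters())
        if set(mine) != set(state):
            missing = set(mine) ^ set(state)
            raise ValueError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in mine.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _param(arr: np.ndarray) -> Tensor:
    return Tensor(arr, requires_grad=True)


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(dtype)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float32, zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((cin, cout), dtype=dtype)
        else:
            w = glorot(rng, (cin, cout), cin, cout, dtype)
        self.w = _param(w)
        self.b = _param(np.zeros(cout, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.w, self.b)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0, dtype=np.float32):
        super().__init__()
        fan_in = kernel * kernel * cin
        fan_out = kernel * kernel * cout
        self.w = _param(glorot(rng, (kernel, kernel, cin, cout), fan_in, fan_out, dtype))
        self.b = _param(np.zeros(cout, dtype=dtype))
        self.stride = stride
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ConvTranspose2x2(Module):
    """2x spatial upsampling by a kernel-2 stride-2 transposed convolution."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.w = _param(glorot(rng, (2, 2, cin, cout), 4 * cin, 4 * cout, dtype))
        self.b = _param(np.zeros(cout, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2x2(x, self.w, self.b)


class LayerNorm(Module):
    """Normalization over the trailing channel axis (channels-last layout)."""

    def __init__(self, dim: int, dtype=np.float32, eps: float = 1e-6):
        super().__init__()
        self.gamma = _param(np.ones(dim, dtype=dtype))
        self.beta = _param(np.zeros(dim, dtype=dtype))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = ad.mean_(x, axis=-1, keepdims=True)
        d = ad.sub(x, mu)
        var = ad.mean_(ad.mul(d, d), axis=-1, keepdims=True)
        inv = ad.pow_(ad.add(var, ad.const(np.asarray(self.eps, dtype=x.dtype))), -0.5)
        return ad.add(ad.mul(ad.mul(d, inv), self.gamma), self.beta)


class Adam:
    """Adam optimizer with bias correction and optional gradient clipping.

    Moments are kept in float64 regardless of the parameter dtype (float32
    squared gradients can overflow during loss spikes); ``clip_norm`` rescales
    the global gradient norm before the update.
    """

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = 5.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]
        self.v = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        grads = [None if p.grad is None else p.grad.astype(np.float64)
                 for p in self.params]
        if self.clip_norm is not None:
            sq = sum(float((g * g).sum()) for g in grads if g is not None)
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
                grads = [None if g is None else g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if g is None:
                continue
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            upd = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data = (p.data - upd).astype(p.data.dtype, copy=False)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
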