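"""DCNv3-based U-Net for 2D PET slice-to-slice translation.

Architecture (stacking-rule parameterization by four hyperparameters
``(C1, C', L1, L3)``):

* stem: two 3x3 convolutions (stride 1, padding 1) to ``C1`` channels with
  layer normalization and GELU — no net downsampling, so stage 1 operates at
  the full 128x128 slice resolution;
* four encoder stages of DCNv3 basic blocks with per-stage channels
  ``C_i = 2^(i-1) * C1``, groups ``G_i = C_i / C'`` and depths
  ``(L1, L1, L3, L1)``; a stride-2 3x3 convolution + LN between stages halves
  resolution and doubles channels; the fourth stage acts as the bottleneck;
* decoder: three upsampling layers, each a 2x2 stride-2 transposed
  convolution, concatenation with the matching encoder stage output (skip
  connection), a 3x3 convolution (padding 1) and layer normalization;
* head: a single 1x1 convolution to one output channel.

The default configuration ``(4, 4, 4, 8)`` yields stage channels
(4, 8, 16, 32), groups (1, 2, 4, 8) and depths (4, 4, 8, 4), and a parameter
count well below the ~2M of the reference design (and orders of magnitude
below 27M-scale attention U-Nets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import autodiff as ad
from .nn import (Conv2d, ConvTranspose2x2, LayerNorm, Module, ModuleList,
                 Tensor)
from .dcnv3 import DCNv3Block


@dataclass
class ModelConfig:
    c1: int = 4
    c_prime: int = 4
    l1: int = 4
    l3: int = 8
    in_channels: int = 2
    out_channels: int = 1
    kernel: int = 3
    ffn_ratio: int = 4
    dtype: str = "float32"

    def __post_init__(self):
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 (PiB) or 2 (PiB+MR)")
        if self.out_channels != 1:
            raise ValueError("out_channels must be 1")
        for i, c in enumerate(self.channels, start=1):
            if c % self.c_prime != 0:
                raise ValueError(
                    f"stage {i} channels {c} not divisible by group dim C'={self.c_prime}")

    @property
    def channels(self) -> tuple:
        return tuple(2 ** i * self.c1 for i in range(4))

    @property
    def groups(self) -> tuple:
        return tuple(c // self.c_prime for c in self.channels)

    @property
    def depths(self) -> tuple:
        return (self.l1, self.l1, self.l3, self.l1)

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


class _Stem(Module):
    def __init__(self, cin: int, cout: int, rng, dtype):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=1, pad=1, dtype=dtype)
        self.norm1 = LayerNorm(cout, dtype)
        self.conv2 = Conv2d(cout, cout, 3, rng, stride=1, pad=1, dtype=dtype)
        self.norm2 = LayerNorm(cout, dtype)

    def forward(self, x):
        return self.norm2(self.conv2(ad.gelu(self.norm1(self.conv1(x)))))


class _Down(Module):
    def __init__(self, cin: int, cout: int, rng, dtype):
        super().__init__()
        self.conv = Conv2d(cin, cout, 3, rng, stride=2, pad=1, dtype=dtype)
        self.norm = LayerNorm(cout, dtype)

    def forward(self, x):
        return self.norm(self.conv(x))


class _Up(Module):
    """Transposed-conv upsampling, skip concatenation, 3x3 conv, LN."""

    def __init__(self, cin: int, skip: int, cout: int, rng, dtype):
        super().__init__()
        self.up = ConvTranspose2x2(cin, cout, rng, dtype)
        self.conv = Conv2d(cout + skip, cout, 3, rng, stride=1, pad=1, dtype=dtype)
        self.norm = LayerNorm(cout, dtype)

    def forward(self, x, skip):
        y = ad.concat([self.up(x), skip], axis=-1)
        return self.norm(self.conv(y))


class Model(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        dt = config.np_dtype
        ch = config.channels
        gr = config.groups
        dp = config.depths

        self.stem = _Stem(config.in_channels, ch[0], rng, dt)
        self.stages = ModuleList(
            ModuleList(DCNv3Block(ch[i], gr[i], rng, config.kernel,
                                  config.ffn_ratio, dt)
                       for _ in range(dp[i]))
            for i in range(4))
        self.downs = ModuleList(_Down(ch[i], ch[i + 1], rng, dt) for i in range(3))
        self.ups = ModuleList(_Up(ch[i + 1], ch[i], ch[i], rng, dt)
                              for i in reversed(range(3)))
        self.head = Conv2d(ch[0], config.out_channels, 1, rng, stride=1, pad=0, dtype=dt)

    def forward(self, x) -> Tensor:
        """Forward an (N, H, W, C) array or Tensor; H and W divisible by 8."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.config.np_dtype))
        if x.shape[-1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {x.shape[-1]}")
        if np.isnan(x.data).any():
            raise ValueError("NaN in network input")

        y = self.stem(x)
        skips = []
        for i in range(4):
            for blk in self.stages[i]:
                y = blk(y)
            if i < 3:
                skips.append(y)
                y = self.downs[i](y)
        for up, skip in zip(self.ups, reversed(skips)):
            y = up(y, skip)
        return self.head(y)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).data


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    """Deterministically initialize a model from ``seed``."""
    return Model(config, np.random.default_rng(seed))


def count_parameters(model: Model) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(model: Model, path) -> None:
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __config__=model.config.to_json(), **state)


def load_checkpoint(path) -> Model:
    with np.load(path, allow_pickle=False) as z:
        config = ModelConfig.from_json(str(z["__config__"]))
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model = build_model(config, seed=0)
    model.load_state_dict(state)
    return model
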