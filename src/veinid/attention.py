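"""Coordinate attention: directional pooling + per-axis sigmoid gates.

The map is average-pooled along each spatial axis separately, giving a
per-(channel, row) and a per-(channel, column) descriptor.  Both pass
through one shared 1×1 encoder (conv → BN → hard-swish), are split back
into their axes, and each axis gets its own 1×1 convolution and sigmoid
to produce gates in (0, 1).  The output is the input scaled by the
outer product of the two gate vectors, so attention carries positional
information along rows and columns instead of a single channel scalar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .nn import BatchNorm2d, Conv2d, HardSwish, Module


@dataclass(frozen=True)
class CoAMConfig:
    channels: int
    reduction: int = 32
    min_mid: int = 8

    @property
    def mid_channels(self) -> int:
        return max(self.min_mid, self.channels // self.reduction)


def directional_pool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average over columns and over rows of an (..., C, H, W) array.

    Returns ``z_h`` with shape (..., C, H) — the per-row means — and
    ``z_w`` with shape (..., C, W) — the per-column means.
    """
    x = np.asarray(x)
    if x.ndim < 2 or x.shape[-1] < 1 or x.shape[-2] < 1:
        raise ValueError("input must have non-empty spatial axes")
    return x.mean(axis=-1), x.mean(axis=-2)


class CoordinateAttention(Module):
    def __init__(self, channels: int, reduction: int = 32, min_mid: int = 8,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.cfg = CoAMConfig(channels, reduction, min_mid)
        mid = self.cfg.mid_channels
        self.encoder = Conv2d(channels, mid, 1, bias=True, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(mid, dtype=dtype)
        self.act = HardSwish()
        self.gate_h = Conv2d(mid, channels, 1, bias=True, rng=rng, dtype=dtype)
        self.gate_w = Conv2d(mid, channels, 1, bias=True, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(
                f"coordinate attention built for {self.cfg.channels} channels, "
                f"got {x.shape[1]}")
        n, c, h, w = x.shape
        z_h = x.mean(axis=3, keepdims=True)                    # (N, C, H, 1)
        z_w = x.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (N, C, W, 1)
        z = concat([z_h, z_w], axis=2)                         # (N, C, H+W, 1)
        z = self.act(self.bn(self.encoder(z)))
        g_h = self.gate_h(z[:, :, :h, :]).sigmoid()            # (N, C, H, 1)
        g_w = self.gate_w(z[:, :, h:, :]).sigmoid()            # (N, C, W, 1)
        return x * g_h * g_w.transpose(0, 1, 3, 2)
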