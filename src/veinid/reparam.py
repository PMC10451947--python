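"""Diverse branch block (DBB) and its exact structural reparameterization.

A DBB trains as four parallel branches — a K×K convolution, a 1×1
convolution, a 1×1→K×K sequence, and a 1×1→K×K-average-pool sequence,
each terminated by batch normalization — whose outputs are summed.  For
deployment the whole block collapses, in closed form, into a single K×K
convolution with bias.  The transforms here are exact linear-algebra
identities on the (frozen) parameters, so the deployed convolution
reproduces the trained block's forward map to floating-point precision.

Two boundary subtleties make the fusion exact rather than approximate:

* a 1×1→K×K sequence applied with "same" padding must pad the
  *intermediate* map with the batch-norm response to a zero input (not
  with zeros) before the valid K×K stage;
* the average-pool branch is expressed as a fixed convolution kernel so
  the same padding rule applies to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import (Tensor, avg_pool_valid, conv2d,
                       pad_with_channel_values as _pad_with_channel_values)
from .nn import BatchNorm2d, Conv2d, Module, Parameter


@dataclass(frozen=True)
class ConvSpec:
    """Geometry of the K×K convolution a DBB stands in for."""
    in_channels: int
    out_channels: int
    kernel_size: int
    stride: int = 1
    padding: int | None = None  # None -> (K-1)//2, shape preserving
    has_bias: bool = True

    def __post_init__(self):
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValueError("kernel size must be odd and positive")
        if self.padding is None:
            object.__setattr__(self, "padding", (self.kernel_size - 1) // 2)


@dataclass
class BNStats:
    """Frozen batch-norm parameters (per-channel)."""
    gamma: np.ndarray
    beta: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    eps: float = 1e-5

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.var = np.asarray(self.var, dtype=np.float64)
        if self.eps < 0:
            raise ValueError("bn eps must be non-negative")
        if np.any(self.var + self.eps <= 0):
            raise ValueError("bn variance + eps must be positive")
        n = len(self.gamma)
        if not (len(self.beta) == len(self.mean) == len(self.var) == n):
            raise ValueError("BN parameter vectors must share one channel count")

    @classmethod
    def from_module(cls, bn: BatchNorm2d) -> "BNStats":
        return cls(bn.gamma.data, bn.beta.data,
                   bn.running_mean, bn.running_var, bn.eps)


@dataclass
class FusedKernel:
    """Weights and bias of a single convolution, the fusion target."""
    weight: np.ndarray  # (out_channels, in_channels, K, K)
    bias: np.ndarray    # (out_channels,)

    def __post_init__(self):
        self.weight = np.asarray(self.weight, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.weight.ndim != 4 or self.weight.shape[2] != self.weight.shape[3]:
            raise ValueError("fused kernel weight must be (O, I, K, K)")
        if self.bias.shape != (self.weight.shape[0],):
            raise ValueError("bias length must equal out_channels")
        if not (np.all(np.isfinite(self.weight)) and np.all(np.isfinite(self.bias))):
            raise ValueError("fused kernel entries must be finite")

    @property
    def kernel_size(self) -> int:
        return self.weight.shape[2]

    def forward(self, x: np.ndarray, stride: int = 1,
                padding: int | None = None) -> np.ndarray:
        """Apply the kernel directly to a NumPy NCHW array (no tape)."""
        if padding is None:
            padding = (self.kernel_size - 1) // 2
        out = conv2d(Tensor(np.asarray(x, dtype=self.weight.dtype)),
                     Tensor(self.weight), Tensor(self.bias),
                     stride=stride, padding=padding)
        return out.data


# ---------------------------------------------------------------------------
# Closed-form transforms
# ---------------------------------------------------------------------------

def fuse_conv_bn(kernel: FusedKernel, bn: BNStats) -> FusedKernel:
    """Fold a trailing batch norm into the convolution.

    ``conv(x; W', b') == BN(conv(x; W, b))`` with
    ``W'_c = W_c * γ_c/√(v_c+ε)`` and ``b'_c = β_c + (b_c − μ_c) γ_c/√(v_c+ε)``.
    """
    if len(bn.gamma) != kernel.weight.shape[0]:
        raise ValueError("BN channel count must equal kernel out_channels")
    scale = bn.gamma / np.sqrt(bn.var + bn.eps)
    weight = kernel.weight * scale[:, None, None, None]
    bias = bn.beta + (kernel.bias - bn.mean) * scale
    return FusedKernel(weight, bias)


def merge_parallel_branches(kernels: list[FusedKernel],
                            k_target: int) -> FusedKernel:
    """Sum parallel branches into one K×K kernel.

    Smaller kernels are zero-padded symmetrically to ``k_target``; with
    "same" padding the forward of the merged kernel equals the sum of
    the branch forwards.
    """
    if k_target % 2 != 1:
        raise ValueError("target kernel size must be odd")
    ref = kernels[0]
    out = np.zeros((ref.weight.shape[0], ref.weight.shape[1],
                    k_target, k_target), dtype=np.float64)
    bias = np.zeros(ref.weight.shape[0], dtype=np.float64)
    for k in kernels:
        if k.weight.shape[:2] != ref.weight.shape[:2]:
            raise ValueError("branches must share in/out channel counts")
        ks = k.kernel_size
        if ks % 2 != 1 or ks > k_target:
            raise ValueError(
                f"branch kernel size {ks} invalid for target {k_target}")
        off = (k_target - ks) // 2
        out[:, :, off:off + ks, off:off + ks] += k.weight
        bias += k.bias
    return FusedKernel(out, bias)


def merge_sequential_1x1_kxk(k1: FusedKernel, k2: FusedKernel) -> FusedKernel:
    """Collapse a 1×1 convolution followed by a K×K convolution.

    Equivalence contract: with the composite applied as
    ``pad(x) → 1×1 (valid) → K×K (valid)`` — i.e. the padded border
    passes through the 1×1 stage, so it carries that stage's bias —
    the returned kernel applied with "same" padding gives the identical
    output.
    """
    if k1.kernel_size != 1:
        raise ValueError("first stage must be a 1×1 kernel")
    if k1.weight.shape[0] != k2.weight.shape[1]:
        raise ValueError("channel chain mismatch between the two stages")
    w1 = k1.weight[:, :, 0, 0]              # (mid, in)
    weight = np.einsum("omhw,mi->oihw", k2.weight, w1)
    bias = k2.bias + np.einsum("omhw,m->o", k2.weight,
                               k1.bias * np.ones(k1.weight.shape[0]))
    return FusedKernel(weight, bias)


def avgpool_as_conv(k: int, channels: int) -> FusedKernel:
    """K×K average pooling expressed as a fixed convolution kernel."""
    if k < 1 or k % 2 != 1:
        raise ValueError("pool size must be odd and positive")
    weight = np.zeros((channels, channels, k, k), dtype=np.float64)
    idx = np.arange(channels)
    weight[idx, idx] = 1.0 / (k * k)
    return FusedKernel(weight, np.zeros(channels, dtype=np.float64))


# ---------------------------------------------------------------------------
# The train-time block
# ---------------------------------------------------------------------------



class DiverseBranchBlock(Module):
    """Train-time four-branch stand-in for a K×K convolution.

    Forward = sum of the four BN-terminated branches.  ``fuse()``
    collapses the block (evaluation mode, running BN statistics) into a
    single :class:`FusedKernel`.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: int = 3, stride: int = 1,
                 eps: float = 1e-5,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng()
        self.spec = ConvSpec(in_channels, out_channels, kernel_size, stride)
        k, p = kernel_size, (kernel_size - 1) // 2
        self.stride = stride
        self.padding = p
        conv = lambda ci, co, kk: Conv2d(ci, co, kk, stride=1, padding=0,
                                         bias=False, rng=rng, dtype=dtype)
        # branch 1: K×K conv -> BN
        self.conv_kxk = Conv2d(in_channels, out_channels, k, stride=stride,
                               padding=p, bias=False, rng=rng, dtype=dtype)
        self.bn_kxk = BatchNorm2d(out_channels, eps=eps, dtype=dtype)
        # branch 2: 1×1 conv -> BN
        self.conv_1x1 = Conv2d(in_channels, out_channels, 1, stride=stride,
                               padding=0, bias=False, rng=rng, dtype=dtype)
        self.bn_1x1 = BatchNorm2d(out_channels, eps=eps, dtype=dtype)
        # branch 3: 1×1 -> BN -> (const pad) -> K×K -> BN
        self.seq_1x1 = conv(in_channels, out_channels, 1)
        self.seq_bn1 = BatchNorm2d(out_channels, eps=eps, dtype=dtype)
        self.seq_kxk = Conv2d(out_channels, out_channels, k, stride=stride,
                              padding=0, bias=False, rng=rng, dtype=dtype)
        self.seq_bn2 = BatchNorm2d(out_channels, eps=eps, dtype=dtype)
        # branch 4: 1×1 -> BN -> (const pad) -> K×K avg pool -> BN
        self.avg_1x1 = conv(in_channels, out_channels, 1)
        self.avg_bn1 = BatchNorm2d(out_channels, eps=eps, dtype=dtype)
        self.avg_kernel = avgpool_as_conv(k, out_channels).weight.astype(dtype)
        self.avg_bn2 = BatchNorm2d(out_channels, eps=eps, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"DBB expects {self.spec.in_channels} channels, got {x.shape[1]}")
        p, s = self.padding, self.stride
        y = self.bn_kxk(self.conv_kxk(x)) + self.bn_1x1(self.conv_1x1(x))

        t = self.seq_bn1(self.seq_1x1(x))
        t = _pad_with_channel_values(t, p, self.seq_bn1.zero_response())
        t = conv2d(t, self.seq_kxk.weight, None, stride=s, padding=0)
        y = y + self.seq_bn2(t)

        a = self.avg_bn1(self.avg_1x1(x))
        a = _pad_with_channel_values(a, p, self.avg_bn1.zero_response())
        a = avg_pool_valid(a, self.spec.kernel_size, stride=s)
        return y + self.avg_bn2(a)

    def fuse(self) -> FusedKernel:
        """Collapse to one K×K kernel using running BN statistics."""
        if self.training:
            raise RuntimeError(
                "fusion requires evaluation mode (fixed BN statistics)")
        k = self.spec.kernel_size
        co = self.spec.out_channels
        b1 = fuse_conv_bn(
            FusedKernel(self.conv_kxk.weight.data, np.zeros(co)),
            BNStats.from_module(self.bn_kxk))
        b2 = fuse_conv_bn(
            FusedKernel(self.conv_1x1.weight.data, np.zeros(co)),
            BNStats.from_module(self.bn_1x1))
        seq_first = fuse_conv_bn(
            FusedKernel(self.seq_1x1.weight.data, np.zeros(co)),
            BNStats.from_module(self.seq_bn1))
        seq_second = fuse_conv_bn(
            FusedKernel(self.seq_kxk.weight.data, np.zeros(co)),
            BNStats.from_module(self.seq_bn2))
        b3 = merge_sequential_1x1_kxk(seq_first, seq_second)
        avg_first = fuse_conv_bn(
            FusedKernel(self.avg_1x1.weight.data, np.zeros(co)),
            BNStats.from_module(self.avg_bn1))
        avg_second = fuse_conv_bn(
            FusedKernel(self.avg_kernel, np.zeros(co)),
            BNStats.from_module(self.avg_bn2))
        b4 = merge_sequential_1x1_kxk(avg_first, avg_second)
        return merge_parallel_branches([b1, b2, b3, b4], k)

    def param_count(self) -> int:
        return sum(p.data.size for p in self.parameters())


def reparameterize_dbb(block: DiverseBranchBlock) -> FusedKernel:
    """Functional alias for :meth:`DiverseBranchBlock.fuse`."""
    return block.fuse()


def fused_to_conv(fk: FusedKernel, stride: int = 1,
                  dtype=np.float32) -> Conv2d:
    """Materialize a fused kernel as a deployable Conv2d module."""
    k = fk.kernel_size
    conv = Conv2d(fk.weight.shape[1], fk.weight.shape[0], k,
                  stride=stride, padding=(k - 1) // 2, bias=True, dtype=dtype)
    conv.weight.data = fk.weight.astype(dtype)
    conv.bias.data = fk.bias.astype(dtype)
    return conv
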