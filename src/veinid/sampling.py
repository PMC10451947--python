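"""Adaptive polyphase sampling (APS): shift-robust 2× downsampling.

A stride-2 decimation of a feature map can start at any of four parity
offsets; translating the input by one pixel permutes those four
"polyphase components".  APS picks the component with the largest Lp
norm (p = 2 by default), so the choice travels with the content and the
downsampled output is consistent under input shifts — exactly so for
even circular shifts, and up to the induced half-resolution shift for
odd ones.

The functional API operates on plain NumPy NCHW arrays; the
:class:`APSDownsample` module wraps the same selection as a
differentiable layer (the gradient flows through the selected
component).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, _make, pad2d
from .nn import Module, max_pool2_stride1

PHASES: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class APSConfig:
    p: float = 2.0          # norm order
    pad_mode: str = "zero"  # padding for odd spatial extents: zero | reflect

    def __post_init__(self):
        if self.p <= 0:
            raise ValueError("norm order p must be positive")
        if self.pad_mode not in ("zero", "reflect"):
            raise ValueError("pad_mode must be 'zero' or 'reflect'")


@dataclass
class PhaseSelection:
    phase_index: tuple[int, int]
    norms: np.ndarray           # 4 non-negative reals, raster phase order
    component: np.ndarray       # the selected half-resolution map


def _pad_to_even(x: np.ndarray, mode: str) -> np.ndarray:
    ph = x.shape[-2] % 2
    pw = x.shape[-1] % 2
    if not (ph or pw):
        return x
    widths = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(x, widths, mode="constant" if mode == "zero" else "reflect")


def polyphase_decompose(x: np.ndarray,
                        cfg: APSConfig = APSConfig()) -> list[np.ndarray]:
    """The four parity sub-grids x[..., i::2, j::2], raster order.

    Odd extents are first padded to even (bottom/right) per the config.
    Together the components tile the (padded) input exactly.
    """
    x = np.asarray(x)
    if x.ndim < 2 or x.shape[-1] < 1 or x.shape[-2] < 1:
        raise ValueError("input must have non-empty spatial extent")
    xp = _pad_to_even(x, cfg.pad_mode)
    return [xp[..., i::2, j::2] for i, j in PHASES]


def _phase_norms(components: list[np.ndarray], p: float) -> np.ndarray:
    flat = [np.abs(c).ravel() for c in components]
    return np.array([(f ** p).sum() ** (1.0 / p) for f in flat])


def select_phase(components: list[np.ndarray],
                 cfg: APSConfig = APSConfig()) -> PhaseSelection:
    """Pick the maximal-Lp-norm component; ties break to the lowest
    raster phase index ((0,0) < (0,1) < (1,0) < (1,1))."""
    if len(components) != 4:
        raise ValueError("expected four polyphase components")
    shape = components[0].shape
    if any(c.shape != shape for c in components):
        raise ValueError("components must share one shape")
    if any(np.isnan(c).any() for c in components):
        raise ValueError("NaN in polyphase component")
    norms = _phase_norms(components, cfg.p)
    best = int(np.argmax(norms))  # argmax returns the first max: raster tie-break
    return PhaseSelection(PHASES[best], norms, components[best])


def aps_downsample(x: np.ndarray, cfg: APSConfig = APSConfig(),
                   pool: str = "none") -> np.ndarray:
    """Downsample 2× by adaptive phase selection.

    ``pool="max"`` first applies 2×2 stride-1 max pooling with same
    padding (the max-pool-replacement form); ``pool="none"`` decimates
    directly (the strided-convolution-replacement form).
    """
    x = np.asarray(x)
    if pool == "max":
        if x.ndim < 2:
            raise ValueError("input must have two spatial axes")
        x4 = x.reshape((-1, 1) + x.shape[-2:])
        x = max_pool2_stride1(Tensor(x4.astype(np.float64))).data.reshape(x.shape)
    elif pool != "none":
        raise ValueError("pool must be 'none' or 'max'")
    return select_phase(polyphase_decompose(x, cfg), cfg).component


# ---------------------------------------------------------------------------
# Differentiable layer
# ---------------------------------------------------------------------------

def aps_select(x: Tensor, p: float = 2.0,
               forced_phase: np.ndarray | None = None
               ) -> tuple[Tensor, np.ndarray]:
    """Per-sample adaptive phase selection on an NCHW tensor.

    The norm is computed over all channels jointly, one choice per
    sample.  ``forced_phase`` (an int array of phase indices, one per
    sample) reuses a selection made elsewhere — e.g. a residual
    shortcut adopting the main path's phase so both half-resolution
    grids stay aligned.  Returns (component, phase indices).
    """
    if x.shape[-2] % 2 or x.shape[-1] % 2:
        x = pad2d(x, (0, x.shape[-2] % 2, 0, x.shape[-1] % 2))
    n = x.shape[0]
    comps_data = [x.data[..., i::2, j::2] for i, j in PHASES]
    if forced_phase is None:
        if p == 2.0:  # fused pass, no temporaries
            norms = np.sqrt(np.stack(
                [np.einsum("nchw,nchw->n", c, c) for c in comps_data]))
        else:
            mags = np.stack([np.abs(c.reshape(n, -1)) ** p
                             for c in comps_data])
            norms = mags.sum(axis=2) ** (1.0 / p)  # (4, N)
        if np.isnan(norms).any():
            raise ValueError("NaN encountered in APS norms")
        phase = np.argmax(norms, axis=0)           # first max: raster tie-break
    else:
        phase = np.asarray(forced_phase, dtype=int)
        if phase.shape != (n,):
            raise ValueError("forced_phase must hold one index per sample")
    out_data = np.empty_like(comps_data[0])
    for k in range(4):
        sel = phase == k
        if sel.any():
            out_data[sel] = comps_data[k][sel]
    out = _make(out_data, (x,))
    if out._parents:
        def bw(g, x=x, phase=phase):
            gx = np.zeros_like(x.data)
            for k, (i, j) in enumerate(PHASES):
                sel = phase == k
                if sel.any():
                    view = gx[..., i::2, j::2]
                    view[sel] += g[sel]
            x._accumulate(gx)
        out._backward = bw
    return out, phase


class APSDownsample(Module):
    """Layer form of APS; optionally reuses an externally chosen phase."""

    def __init__(self, p: float = 2.0):
        super().__init__()
        if p <= 0:
            raise ValueError("norm order p must be positive")
        self.p = p

    def forward(self, x: Tensor,
                forced_phase: np.ndarray | None = None
                ) -> tuple[Tensor, np.ndarray]:
        return aps_select(x, self.p, forced_phase)
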