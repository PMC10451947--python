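"""Elastic angular-margin softmax loss on L2-normalized embeddings.

The classifier is bias-free and both the embeddings x_i and the class
weight rows W_j are L2-normalized, so the logit for class j is the
cosine of the angle θ_j between them, scaled by s.  The target class
logit receives an additive *angular* margin drawn per sample from
N(m, σ²):

    L = −(1/N) Σ_i log  e^{s·cos(θ_{y_i} + E_i)}
                        ───────────────────────────────────────
                        e^{s·cos(θ_{y_i} + E_i)} + Σ_{j≠y_i} e^{s·cos θ_j}

With σ = 0 this is exactly the additive-angular-margin (ArcFace-style)
softmax; the Gaussian spread lets the effective margin vary between
samples.  cos(θ+E) is expanded as cosθ·cosE − sinθ·sinE with
sinθ = √(1 − cos²θ) so no arccos is ever taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import l2_normalize


@dataclass(frozen=True)
class EMLConfig:
    s: float = 64.0       # logit scale
    m: float = 0.5        # margin mean, radians
    sigma: float = 0.05   # margin spread, radians
    n: int | None = None  # number of classes (None -> taken from weights)

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("scale s must be positive")
        if not 0.0 <= self.m < np.pi:
            raise ValueError("margin mean must lie in [0, π)")
        if self.sigma < 0:
            raise ValueError("margin spread must be non-negative")


def sample_margin(m: float, sigma: float, rng: np.random.Generator,
                  size=None) -> np.ndarray | float:
    """One independent Gaussian margin draw per sample per step."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return m if size is None else np.full(size, m)
    return rng.normal(m, sigma, size=size)


def eml_loss(embeddings: Tensor, labels: np.ndarray, weights: Tensor,
             cfg: EMLConfig, rng: np.random.Generator) -> Tensor:
    """Elastic-margin loss for a batch.

    ``embeddings``: (N, d), need not be pre-normalized.  ``weights``:
    (n_classes, d) classifier rows, need not be pre-normalized.
    Computed with max-logit subtraction for numerical stability.
    """
    labels = np.asarray(labels)
    n_classes = weights.shape[0]
    if cfg.n is not None and cfg.n != n_classes:
        raise ValueError("config class count disagrees with weight rows")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise IndexError("label out of range")
    n = embeddings.shape[0]

    x = l2_normalize(embeddings, axis=1)
    w = l2_normalize(weights, axis=1)
    cos = x @ w.transpose(1, 0)                     # (N, n_classes)

    onehot = np.zeros((n, n_classes), dtype=cos.data.dtype)
    onehot[np.arange(n), labels] = 1.0
    onehot_t = Tensor(onehot)

    ct = (cos * onehot_t).sum(axis=1, keepdims=True)  # cos θ_target, (N, 1)
    margins = np.atleast_1d(sample_margin(cfg.m, cfg.sigma, rng, size=n)) \
        .astype(cos.data.dtype).reshape(n, 1)
    cos_e = Tensor(np.cos(margins))
    sin_e = Tensor(np.sin(margins))
    sin_t = ((1.0 - ct * ct).clip(0.0, 1.0) + 1e-12).sqrt()
    delta = ct * cos_e - sin_t * sin_e - ct          # cos(θ+E) − cosθ, (N, 1)

    logits = cfg.s * (cos + onehot_t * delta)
    rowmax = Tensor(logits.data.max(axis=1, keepdims=True))
    shifted = logits - rowmax
    lse = shifted.exp().sum(axis=1, keepdims=True).log()
    target_logit = (shifted * onehot_t).sum(axis=1, keepdims=True)
    return (lse - target_logit).mean()


def cosine_cross_entropy(embeddings: Tensor, labels: np.ndarray,
                         weights: Tensor, s: float,
                         rng: np.random.Generator | None = None) -> Tensor:
    """Margin-free softmax cross-entropy on scaled cosine logits
    (the m = 0, σ = 0 degeneration; used by the ablation baseline)."""
    cfg = EMLConfig(s=s, m=0.0, sigma=0.0)
    return eml_loss(embeddings, labels, weights, cfg,
                    rng or np.random.default_rng())
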