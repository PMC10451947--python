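"""Neural-network building blocks over the autodiff engine.

Layers follow the familiar module pattern: parameters are discovered by
walking attributes (lists of modules included), ``train()``/``eval()``
toggle batch-norm and dropout behaviour, and ``state_dict`` /
``load_state_dict`` give flat name→array views for checkpointing.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv2d, pad2d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    def __init__(self) -> None:
        self.training = True

    # -- traversal ------------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    # -- mode -----------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state ----------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.array(state[name], dtype=p.data.dtype)
        for name, _ in list(self.named_buffers()):
            owner, attr = self._resolve(name)
            setattr(owner, attr, np.array(state[name]))

    def _resolve(self, dotted: str) -> tuple["Module", str]:
        obj: Module = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            if part.isdigit():
                obj = obj[int(part)] if isinstance(obj, (list, tuple)) else vars(obj)[part]
            else:
                value = vars(obj)[part]
                obj = value
        return obj, parts[-1]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """Plain 2-D convolution (cross-correlation), Kaiming-initialized."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(
            0.0, std, (out_channels, in_channels, kernel_size, kernel_size)
        ).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1, dtype=np.float32):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.num_features:
            raise ValueError(
                f"BatchNorm2d({self.num_features}) got {x.shape[1]} channels")
        from .autodiff import batch_norm
        if self.training:
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            mean = np.einsum("nchw->c", x.data) / n
            mean_sq = np.einsum("nchw,nchw->c", x.data, x.data) / n
            var = np.maximum(mean_sq - mean * mean, 0.0)
            m = self.momentum
            unbiased = var * (n / max(n - 1, 1))
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var
                                + m * unbiased).astype(self.running_var.dtype)
            return batch_norm(x, self.gamma, self.beta, mean, var,
                              self.eps, batch_stats=True)
        return batch_norm(x, self.gamma, self.beta,
                          self.running_mean.astype(x.data.dtype),
                          self.running_var.astype(x.data.dtype),
                          self.eps, batch_stats=False)

    def zero_response(self) -> Tensor:
        """BN output for an all-zero input, from running statistics.

        Used to pad intermediate maps so that sequential-branch fusion
        stays exact at the borders.
        """
        denom = np.sqrt(self.running_var + self.eps)
        return self.beta - self.gamma * Tensor(self.running_mean / denom)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class HardSwish(Module):
    """x * relu6(x + 3) / 6 — the activation used inside coordinate attention."""

    def forward(self, x: Tensor) -> Tensor:
        return x * (x + 3.0).clip(0.0, 6.0) * (1.0 / 6.0)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.data.dtype)
        return x * Tensor(keep / (1.0 - self.p))


def max_pool2_stride1(x: Tensor) -> Tensor:
    """2×2 max pooling with stride 1 and same (bottom/right) padding."""
    from .autodiff import maximum
    xp = pad2d(x, (0, 1, 0, 1), value=-np.inf)
    h, w = x.shape[-2], x.shape[-1]
    a = xp[..., 0:h, 0:w]
    b = xp[..., 0:h, 1:w + 1]
    c = xp[..., 1:h + 1, 0:w]
    d = xp[..., 1:h + 1, 1:w + 1]
    return maximum(maximum(a, b), maximum(c, d))


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3))


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm_sq = (x * x).sum(axis=axis, keepdims=True)
    if np.any(norm_sq.data <= 0):
        raise ValueError("cannot L2-normalize a zero vector")
    return x / (norm_sq + eps).sqrt()
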