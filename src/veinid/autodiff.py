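"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operator set the network needs: broadcasted
elementwise arithmetic, matrix multiplication, reductions, basic-slice
indexing, padding/concatenation/reshaping, the usual activations, and a
2-D cross-correlation primitive (``conv2d``) implemented with an
im2col/GEMM lowering.  Gradients propagate through a dynamically built
tape; ``Tensor.backward`` runs a topological sweep.

Arrays keep whatever floating dtype they are given, so the same graph
can be evaluated in float32 (training) or float64 (equivalence audits).
"""

from __future__ import annotations

import contextlib
from typing import Sequence

import numpy as np
from scipy.linalg import blas as _blas

__all__ = [
    "Tensor",
    "as_tensor",
    "avg_pool_valid",
    "batch_norm",
    "concat",
    "conv2d",
    "maximum",
    "pad2d",
    "profile_macs",
    "no_grad",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class _MacCounter:
    __slots__ = ("macs",)

    def __init__(self) -> None:
        self.macs = 0


_PROFILE: _MacCounter | None = None


@contextlib.contextmanager
def profile_macs():
    """Count multiply-accumulates of conv2d/matmul executed in the block.

    The convention is one MAC per scalar multiply in the direct
    (non-im2col) formulation: ``K^2 * Cin * Cout * Hout * Wout`` for a
    convolution and ``M * K * N`` for a matrix product.
    """
    global _PROFILE
    prev = _PROFILE
    _PROFILE = counter = _MacCounter()
    try:
        yield counter
    finally:
        _PROFILE = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype.kind not in "f":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None,
                 free_graph: bool = False) -> None:
        """Backpropagate to every leaf that requires a gradient.

        With ``free_graph=True`` interior activations and gradients are
        released as soon as they have been consumed (children precede
        parents in the sweep), which roughly halves peak memory during
        training; the graph cannot be backpropagated again afterwards.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # interior node: its gradient has been consumed
                node.grad = None
                if free_graph:
                    node.data = None
                    node._backward = None
                    node._parents = ()

    # -- operator overloads ---------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)))

    def __rsub__(self, other):
        return as_tensor(other, like=self) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: (_unbroadcast(g * b.data, a.shape),
                                        _unbroadcast(g * a.data, b.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: (_unbroadcast(g / b.data, a.shape),
                                        _unbroadcast(-g * a.data / (b.data ** 2), b.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) / self

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = _make(np.power(self.data, exponent), (self,))
        if out._parents:
            def bw(g, a=self, e=exponent):
                a._accumulate(g * e * np.power(a.data, e - 1))
            out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other, like=self)
        if _PROFILE is not None:
            m = int(np.prod(self.data.shape[:-1]))
            _PROFILE.macs += m * self.data.shape[-1] * other.data.shape[-1]
        out = _make(self.data @ other.data, (self, other))
        if out._parents:
            def bw(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
                if b.requires_grad or b._parents:
                    b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))
            out._backward = bw
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out._parents:
            def bw(g, a=self, idx=idx):
                full = np.zeros_like(a.data)
                full[idx] += g
                a._accumulate(full)
            out._backward = bw
        return out

    # -- unary math -----------------------------------------------------------
    def exp(self):
        out = _make(np.exp(self.data), (self,))
        if out._parents:
            def bw(g, a=self, o=out):
                a._accumulate(g * o.data)
            out._backward = bw
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._parents:
            def bw(g, a=self):
                a._accumulate(g / a.data)
            out._backward = bw
        return out

    def sqrt(self):
        out = _make(np.sqrt(self.data), (self,))
        if out._parents:
            def bw(g, a=self, o=out):
                a._accumulate(g * 0.5 / o.data)
            out._backward = bw
        return out

    def relu(self):
        out = _make(np.maximum(self.data, 0), (self,))
        if out._parents:
            def bw(g, a=self):
                a._accumulate(g * (a.data > 0))
            out._backward = bw
        return out

    def sigmoid(self):
        with np.errstate(over="ignore"):
            val = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(val, (self,))
        if out._parents:
            def bw(g, a=self, o=out):
                a._accumulate(g * o.data * (1.0 - o.data))
            out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        out = _make(np.clip(self.data, lo, hi), (self,))
        if out._parents:
            def bw(g, a=self, lo=lo, hi=hi):
                a._accumulate(g * ((a.data >= lo) & (a.data <= hi)))
            out._backward = bw
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def bw(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.shape).astype(a.data.dtype))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            def bw(g, a=self):
                a._accumulate(g.reshape(a.shape))
            out._backward = bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = _make(self.data.transpose(axes), (self,))
        if out._parents:
            inv = np.argsort(axes)
            def bw(g, a=self, inv=tuple(inv)):
                a._accumulate(g.transpose(inv))
            out._backward = bw
        return out


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
    return out


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else np.float32
    return Tensor(np.asarray(x, dtype=dtype))


def _binary(a: Tensor, b, fwd, grads) -> Tensor:
    b = as_tensor(b, like=a)
    out = _make(fwd(a.data, b.data), (a, b))
    if out._parents:
        def bw(g, a=a, b=b, grads=grads):
            ga, gb = grads(g, a, b)
            if a.requires_grad or a._parents:
                a._accumulate(ga)
            if b.requires_grad or b._parents:
                b._accumulate(gb)
        out._backward = bw
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise maximum; ties route the gradient to the first argument."""
    return _binary(a, b, np.maximum,
                   lambda g, a, b: (_unbroadcast(g * (a.data >= b.data), a.shape),
                                    _unbroadcast(g * (a.data < b.data), b.shape)))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        def bw(g, tensors=tensors, sizes=sizes, axis=axis):
            offset = 0
            for t, s in zip(tensors, sizes):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + s)
                if t.requires_grad or t._parents:
                    t._accumulate(g[tuple(sl)])
                offset += s
        out._backward = bw
    return out


def pad2d(x: Tensor, pad: int | tuple[int, int, int, int], value: float = 0.0) -> Tensor:
    """Pad the two trailing (spatial) axes of an NCHW tensor.

    ``pad`` is either a single symmetric width or ``(top, bottom, left,
    right)``.
    """
    if isinstance(pad, int):
        top = bottom = left = right = pad
    else:
        top, bottom, left, right = pad
    if min(top, bottom, left, right) < 0:
        raise ValueError("negative padding is not supported")
    widths = [(0, 0)] * (x.ndim - 2) + [(top, bottom), (left, right)]
    out = _make(np.pad(x.data, widths, constant_values=value), (x,))
    if out._parents:
        def bw(g, a=x, top=top, bottom=bottom, left=left, right=right):
            h, w = a.shape[-2], a.shape[-1]
            a._accumulate(g[..., top:top + h, left:left + w])
        out._backward = bw
    return out


def pad_with_channel_values(x: Tensor, pad: int, values: Tensor) -> Tensor:
    """Spatially pad an NCHW tensor, filling the border with a
    per-channel constant (one tape node; gradient flows to both the
    map and the constants)."""
    if pad == 0:
        return x
    n, c, h, w = x.shape
    xp = np.pad(x.data, [(0, 0), (0, 0), (pad, pad), (pad, pad)])
    v = values.data.reshape(1, c, 1, 1)
    xp[:, :, :pad, :] = v
    xp[:, :, h + pad:, :] = v
    xp[:, :, pad:h + pad, :pad] = v
    xp[:, :, pad:h + pad, w + pad:] = v
    out = _make(xp, (x, values))
    if out._parents:
        def bw(g, x=x, values=values, pad=pad, h=h, w=w):
            if x.requires_grad or x._parents:
                x._accumulate(g[:, :, pad:pad + h, pad:pad + w])
            if values.requires_grad or values._parents:
                border = g.sum(axis=(0, 2, 3)) \
                    - g[:, :, pad:pad + h, pad:pad + w].sum(axis=(0, 2, 3))
                values._accumulate(border.reshape(values.shape))
        out._backward = bw
    return out


def avg_pool_valid(x: Tensor, k: int, stride: int = 1) -> Tensor:
    """K×K average pooling, valid (no padding), per channel."""
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError("input smaller than the pooling window")
    out_data = np.zeros((n, c, ho, wo), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            out_data += x.data[:, :, i:i + stride * (ho - 1) + 1:stride,
                               j:j + stride * (wo - 1) + 1:stride]
    out_data *= 1.0 / (k * k)
    out = _make(out_data, (x,))
    if out._parents:
        def bw(g, x=x, k=k, stride=stride, ho=ho, wo=wo):
            gx = np.zeros_like(x.data)
            gs = g * (1.0 / (k * k))
            for i in range(k):
                for j in range(k):
                    gx[:, :, i:i + stride * (ho - 1) + 1:stride,
                       j:j + stride * (wo - 1) + 1:stride] += gs
            x._accumulate(gx)
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Fused batch-norm primitive
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               mean: np.ndarray, var: np.ndarray, eps: float,
               batch_stats: bool) -> Tensor:
    """Per-channel normalization of an NCHW tensor in one tape node.

    ``mean``/``var`` are the (already computed) per-channel statistics;
    ``batch_stats`` says whether they came from this batch (training —
    the gradient then includes the statistics' dependence on x) or are
    frozen running values (inference).  Fusing the whole affine
    normalization into a single node keeps the tape small.
    """
    inv = (1.0 / np.sqrt(var + eps)).astype(x.data.dtype)
    mean = mean.astype(x.data.dtype)
    scale = gamma.data * inv
    shift = beta.data - mean * scale
    out_data = x.data * scale[None, :, None, None] + shift[None, :, None, None]
    out = _make(out_data, (x, gamma, beta))
    if out._parents:
        def bw(g, x=x, gamma=gamma, beta=beta, mean=mean, inv=inv,
               batch_stats=batch_stats):
            # per-channel sums via fused einsum passes; xhat-based terms
            # are expanded so no full-size temporary is ever stored
            s1 = np.einsum("nchw->c", g)
            sx = np.einsum("nchw,nchw->c", g, x.data)
            dgamma = (sx - mean * s1) * inv
            if beta.requires_grad or beta._parents:
                beta._accumulate(s1)
            if gamma.requires_grad or gamma._parents:
                gamma._accumulate(dgamma)
            if x.requires_grad or x._parents:
                sc = gamma.data * inv
                if batch_stats:
                    count = g.shape[0] * g.shape[2] * g.shape[3]
                    gx_mean = dgamma / count
                    a = -sc * inv * gx_mean
                    const = -sc * s1 / count + sc * gx_mean * inv * mean
                    dx = g * sc[None, :, None, None]
                    dx += x.data * a[None, :, None, None]
                    dx += const[None, :, None, None]
                    x._accumulate(dx)
                else:
                    x._accumulate(g * sc[None, :, None, None])
        out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Convolution primitive
# ---------------------------------------------------------------------------

def _to_nhwc_padded(x: np.ndarray, padding: int) -> np.ndarray:
    xt = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
    if padding:
        xt = np.pad(xt, [(0, 0), (padding, padding), (padding, padding), (0, 0)])
    return xt


def _tap_view(xt: np.ndarray, i: int, j: int, ho: int, wo: int,
              stride: int) -> np.ndarray:
    return xt[:, i:i + stride * (ho - 1) + 1:stride,
              j:j + stride * (wo - 1) + 1:stride, :]


def _gemm_acc(out_c: np.ndarray, a_c: np.ndarray, b_c: np.ndarray) -> None:
    """out += a @ b on C-contiguous float32/float64 2-D arrays, in place.

    Runs BLAS on the transposed problem (outᵀ = bᵀ aᵀ), for which all
    three C-order arrays are already Fortran-contiguous — no copies, no
    temporary for the accumulation.
    """
    gemm = _blas.sgemm if out_c.dtype == np.float32 else _blas.dgemm
    gemm(1.0, b_c.T, a_c.T, beta=1.0, c=out_c.T, overwrite_c=True)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
                  stride: int, padding: int,
                  xt: np.ndarray | None = None) -> np.ndarray:
    """Shift-and-GEMM convolution: one (N·Ho·Wo, C) × (C, O) product per
    spatial tap on a channels-last copy of the input.  This keeps every
    copy a long-contiguous-chunk move, which is what NumPy is fast at."""
    n, c, h, wd = x.shape
    o, _, kh, kw = w.shape
    if xt is None:
        xt = _to_nhwc_padded(x, padding)
    hp, wp = xt.shape[1:3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    out = np.zeros((n * ho * wo, o), dtype=x.dtype)
    if b is not None:
        out[:] = b
    wt = np.ascontiguousarray(w.transpose(2, 3, 1, 0))  # (K, K, C, O)
    use_blas = x.dtype in (np.float32, np.float64)
    for i in range(kh):
        for j in range(kw):
            xs = _tap_view(xt, i, j, ho, wo, stride).reshape(-1, c)
            if use_blas:
                _gemm_acc(out, xs, wt[i, j])
            else:
                out += xs @ wt[i, j]
    if _PROFILE is not None:
        _PROFILE.macs += kh * kw * c * o * ho * wo * n
    return np.ascontiguousarray(out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation over an NCHW tensor.

    ``w`` has shape (out_channels, in_channels, K, K).  The backward
    pass lowers the input gradient to another stride-1 correlation with
    the spatially flipped, channel-transposed kernel (gradients are
    scattered onto the stride grid first when ``stride > 1``).
    """
    if x.ndim != 4 or w.ndim != 4:
        raise ValueError("conv2d expects NCHW input and OIKK weights")
    if x.shape[1] != w.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]}, kernel expects {w.shape[1]}")
    parents = (x, w) if b is None else (x, w, b)
    out_data = _conv_forward(x.data, w.data,
                             None if b is None else b.data, stride, padding)
    out = _make(out_data, parents)
    if out._parents:
        def bw(g, x=x, w=w, b=b, stride=stride, padding=padding):
            n, c, h, wd = x.shape
            o, _, kh, kw = w.shape
            _, _, ho, wo = g.shape
            if b is not None and (b.requires_grad or b._parents):
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad or w._parents:
                xt = _to_nhwc_padded(x.data, padding)  # cheaper than keeping it
                gmat = np.ascontiguousarray(
                    g.transpose(0, 2, 3, 1)).reshape(-1, o)
                dw = np.empty_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        xs = _tap_view(xt, i, j, ho, wo, stride)
                        dw[:, :, i, j] = gmat.T @ xs.reshape(-1, c)
                w._accumulate(dw)
            if x.requires_grad or x._parents:
                # scatter g to the stride-1 grid, then full correlation
                hs = h + 2 * padding - kh + 1
                ws = wd + 2 * padding - kw + 1
                if stride == 1:
                    gd = g
                else:
                    gd = np.zeros((n, o, hs, ws), dtype=g.dtype)
                    gd[:, :, ::stride, ::stride] = g
                wflip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                gx = _conv_forward(gd, wflip, None, 1, max(kh - 1, kw - 1))
                if padding:
                    gx = gx[:, :, padding:padding + h, padding:padding + wd]
                x._accumulate(gx)
        out._backward = bw
    return out
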