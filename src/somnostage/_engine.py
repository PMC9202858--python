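"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package's networks are small 1-D convolutional/recurrent models, so the
engine only implements the primitives they need: broadcast arithmetic,
matmul, 1-D convolution and pooling (im2col + BLAS), batch normalisation,
the usual pointwise nonlinearities, dropout and a fused softmax
cross-entropy.  Gradients are accumulated on a tape and replayed in reverse
topological order.  Everything is dtype-preserving; parameters default to
float32, while gradient-check tests may run the same graph in float64.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "no_grad",
    "add",
    "mul",
    "matmul",
    "relu",
    "selu",
    "sigmoid",
    "tanh",
    "conv1d",
    "max_pool1d",
    "mean",
    "amax",
    "concat",
    "reshape",
    "narrow",
    "dropout",
    "softmax_cross_entropy",
    "softmax",
    "Conv1d",
    "Linear",
    "BatchNorm1d",
    "Dropout",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _sum_to(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward: Callable | None = None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ---------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        # iterative topological sort (graphs can be a few thousand nodes deep)
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __matmul__(self, other):
        return matmul(self, other)


class Parameter(Tensor):
    """A trainable tensor (float32 by default)."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents: Sequence[Tensor], backward: Callable | None) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    if not req:
        return Tensor(data)
    return Tensor(data, requires_grad=True, _parents=tuple(parents), _backward=backward)


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_sum_to(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_sum_to(g, b.data.shape))

    return _make(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_sum_to(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_sum_to(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bwd)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_sum_to(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_sum_to(gb, b.data.shape))

    return _make(out_data, (a, b), bwd)


def relu(x) -> Tensor:
    x = _as_tensor(x)
    out_data = np.maximum(x.data, 0)

    def bwd(g):
        x._accumulate(g * (x.data > 0))

    return _make(out_data, (x,), bwd)


_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def selu(x) -> Tensor:
    x = _as_tensor(x)
    pos = x.data > 0
    expx = np.exp(np.minimum(x.data, 0.0))
    out_data = _SELU_SCALE * np.where(pos, x.data, _SELU_ALPHA * (expx - 1.0))

    def bwd(g):
        dx = _SELU_SCALE * np.where(pos, 1.0, _SELU_ALPHA * expx)
        x._accumulate(g * dx.astype(x.data.dtype))

    return _make(out_data.astype(x.data.dtype), (x,), bwd)


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    with np.errstate(over="ignore"):   # exp overflow saturates cleanly to 0
        s = 1.0 / (1.0 + np.exp(-x.data))
    s = s.astype(x.data.dtype)

    def bwd(g):
        x._accumulate(g * s * (1.0 - s))

    return _make(s, (x,), bwd)


def tanh(x) -> Tensor:
    x = _as_tensor(x)
    t = np.tanh(x.data)

    def bwd(g):
        x._accumulate(g * (1.0 - t * t))

    return _make(t, (x,), bwd)


def reshape(x, shape) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.reshape(shape)

    def bwd(g):
        x._accumulate(g.reshape(x.data.shape))

    return _make(out_data, (x,), bwd)


def narrow(x, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` entries starting at ``start`` along ``axis``."""
    x = _as_tensor(x)
    idx = [slice(None)] * x.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out_data = x.data[idx]

    def bwd(g):
        full = np.zeros_like(x.data)
        full[idx] = g
        x._accumulate(full)

    return _make(out_data, (x,), bwd)


def concat(tensors: Sequence, axis: int) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(out_data, tuple(ts), bwd)


def mean(x, axis: int, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.mean(axis=axis, keepdims=keepdims)
    n = x.data.shape[axis]

    def bwd(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g / n, x.data.shape).astype(x.data.dtype))

    return _make(out_data, (x,), bwd)


def amax(x, axis: int, keepdims: bool = False) -> Tensor:
    """Max along one axis; the gradient routes to the first argmax (ties)."""
    x = _as_tensor(x)
    out_data = x.data.max(axis=axis, keepdims=keepdims)
    arg = np.argmax(x.data, axis=axis)

    def bwd(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        full = np.zeros_like(x.data)
        np.put_along_axis(full, np.expand_dims(arg, axis), g, axis=axis)
        x._accumulate(full)

    return _make(out_data, (x,), bwd)


def conv1d(x, weight, bias=None, stride: int = 1, padding: int = 0) -> Tensor:
    """1-D cross-correlation.  x: (B, C, T), weight: (F, C, K) -> (B, F, T_out)."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    if bias is not None:
        bias = _as_tensor(bias)
    B, C, T = x.data.shape
    F, Cw, K = weight.data.shape
    if C != Cw:
        raise ValueError(f"conv1d channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    Tp = xp.shape[2]
    T_out = (Tp - K) // stride + 1
    if T_out < 1:
        raise ValueError(f"conv1d: input length {T} too short for kernel {K}")
    # (B, C, T_out, K) windows -> (B, T_out, C*K)
    win = sliding_window_view(xp, K, axis=2)[:, :, ::stride][:, :, :T_out]
    cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B, T_out, C * K)
    wmat = weight.data.reshape(F, C * K)
    out = cols @ wmat.T  # (B, T_out, F)
    if bias is not None:
        out = out + bias.data
    out_data = np.ascontiguousarray(out.transpose(0, 2, 1))

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 1))  # (B, T_out, F)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gt.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = gt.reshape(-1, F).T @ cols.reshape(-1, C * K)
            weight._accumulate(gw.reshape(F, C, K))
        if x.requires_grad:
            gcols = (gt @ wmat).reshape(B, T_out, C, K).transpose(0, 2, 1, 3)
            gxp = np.zeros_like(xp)
            base = stride * np.arange(T_out)
            for k in range(K):
                gxp[:, :, base + k] += gcols[:, :, :, k]
            if padding:
                gxp = gxp[:, :, padding:Tp - padding]
            x._accumulate(gxp)

    return _make(out_data, parents, bwd)


def max_pool1d(x, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Max pooling over time.  Padded positions use -inf and never win."""
    x = _as_tensor(x)
    B, C, T = x.data.shape
    if padding:
        fill = np.finfo(x.data.dtype).min if np.issubdtype(x.data.dtype, np.floating) else np.iinfo(x.data.dtype).min
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)), constant_values=fill)
    else:
        xp = x.data
    Tp = xp.shape[2]
    T_out = (Tp - kernel) // stride + 1
    win = sliding_window_view(xp, kernel, axis=2)[:, :, ::stride][:, :, :T_out]
    arg = np.argmax(win, axis=3)  # (B, C, T_out)
    out_data = np.take_along_axis(win, arg[..., None], axis=3)[..., 0]

    def bwd(g):
        gxp = np.zeros_like(xp)
        pos = stride * np.arange(T_out) + arg  # (B, C, T_out) absolute indices
        np.add.at(gxp.reshape(B * C, Tp),
                  (np.repeat(np.arange(B * C), T_out), pos.reshape(B * C, T_out).ravel()),
                  g.reshape(B * C, T_out).ravel())
        if padding:
            gxp = gxp[:, :, padding:Tp - padding]
        x._accumulate(gxp)

    return _make(np.ascontiguousarray(out_data), (x,), bwd)


def dropout(x, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    x = _as_tensor(x)
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out_data = x.data * keep

    def bwd(g):
        x._accumulate(g * keep)

    return _make(out_data, (x,), bwd)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain numpy softmax (used outside the graph, e.g. at inference)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy between row-wise softmax(logits) and target rows.

    ``targets`` is a plain (N, k) array of probability rows (e.g. smoothed
    labels); gradient is (softmax - targets) / N.
    """
    logits = _as_tensor(logits)
    t = np.asarray(targets, dtype=logits.data.dtype)
    if t.shape != logits.data.shape:
        raise ValueError(f"target shape {t.shape} != logits shape {logits.data.shape}")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logq = z - logsumexp
    n = logits.data.shape[0]
    out_data = np.asarray(-(t * logq).sum() / n, dtype=logits.data.dtype)
    q = np.exp(logq)

    def bwd(g):
        logits._accumulate(g * (q - t) / n)

    return _make(out_data, (logits,), bwd)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Light-weight container with named parameters, buffers and train mode."""

    def __init__(self):
        self.training = True
        self._buffer_names: tuple[str, ...] = ()

    # attribute scan keeps the class free of registration boilerplate
    def _children(self) -> Iterable[tuple[str, "Module"]]:
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in self._buffer_names:
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(f"{prefix}{name}.")

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for _, child in self._children():
            child.set_training(flag)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer.{k}": np.asarray(v).copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, arr in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r} in state dict")
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = arr.astype(params[name].data.dtype).copy()
            elif kind == "buffer":
                obj = self
                *path, attr = name.split(".")
                for part in path:
                    obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
                setattr(obj, attr, arr.copy())
            else:
                raise KeyError(f"unrecognised state key {key!r}")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        std = math.sqrt(2.0 / (in_channels * kernel))
        self.weight = Parameter(rng.normal(0.0, std, (out_channels, in_channels, kernel)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv1d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = math.sqrt(1.0 / in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x):
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = add(out, self.bias)
        return out


class BatchNorm1d(Module):
    """Batch normalisation over (batch, time) per channel for (B, C, T) maps."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 affine: bool = True):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.affine = affine
        if affine:
            self.gamma = Parameter(np.ones(num_features, dtype=np.float32))
            self.beta = Parameter(np.zeros(num_features, dtype=np.float32))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x):
        x = _as_tensor(x)
        B, C, T = x.data.shape
        if self.training:
            mu = x.data.mean(axis=(0, 2))
            var = x.data.var(axis=(0, 2))
            n = B * T
            unbias = var * n / max(n - 1, 1)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbias).astype(np.float32)
        else:
            mu = self.running_mean.astype(x.data.dtype)
            var = self.running_var.astype(x.data.dtype)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None]) * invstd[None, :, None]
        xhat = xhat.astype(x.data.dtype)
        if self.affine:
            gamma, beta = self.gamma, self.beta
            out_data = gamma.data[None, :, None] * xhat + beta.data[None, :, None]
            parents = (x, gamma, beta)
        else:
            gamma = beta = None
            out_data = xhat
            parents = (x,)
        training = self.training
        n = B * T

        def bwd(g):
            if gamma is not None:
                if gamma.requires_grad:
                    gamma._accumulate((g * xhat).sum(axis=(0, 2)))
                if beta.requires_grad:
                    beta._accumulate(g.sum(axis=(0, 2)))
                gscale = gamma.data[None, :, None]
            else:
                gscale = 1.0
            if x.requires_grad:
                gy = g * gscale
                if training:
                    s1 = gy.sum(axis=(0, 2), keepdims=True)
                    s2 = (gy * xhat).sum(axis=(0, 2), keepdims=True)
                    dx = (invstd[None, :, None] / n) * (n * gy - s1 - xhat * s2)
                else:
                    dx = gy * invstd[None, :, None]
                x._accumulate(dx.astype(x.data.dtype))

        return _make(out_data, parents, bwd)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        return dropout(x, self.p, self.rng, self.training)
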