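"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

This is the tensor backend for the phase-velocity regression network: a
:class:`Tensor` wrapping an ndarray with a gradient slot, a set of primitive
operations (broadcast arithmetic, matmul, 2-D convolutions, batch norm, GELU,
softmax, rotary embedding) each carrying a hand-written backward rule, small
``Module``/layer classes, and an Adam optimizer.  Convolutions are lowered to
BLAS matmuls via im2col; the depthwise 3×3 kernel uses the nine-shift form.

Scope is deliberately minimal: exactly the operations the network needs, CPU
only, float32 by default (switchable to float64 for high-accuracy checks),
verified against central-difference gradients in the test suite.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor", "no_grad", "add", "mul", "matmul", "reshape", "transpose", "mean",
    "gelu", "softmax", "conv2d", "dwconv3x3", "conv1x1", "batchnorm2d",
    "rope", "Module", "Parameter", "Linear", "Conv2d", "DWConv3x3", "Conv1x1",
    "BatchNorm2d", "Adam", "mse_loss",
]

_grad_enabled = True
_dtype = np.float32


def set_default_dtype(dtype) -> None:
    """Set the engine's working precision (float32 default; float64 for
    high-accuracy checks)."""
    global _dtype
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be np.float32 or np.float64")
    _dtype = dtype


def get_default_dtype():
    return _dtype


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (validation / inference)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], tuple[np.ndarray | None, ...]] | None = None

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not (parent.requires_grad or parent._parents):
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    # operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _wrap(-1.0)))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], tuple[np.ndarray | None, ...]]) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# primitives


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data
    return _make(data, (a, b), lambda g: (_unbroadcast(g, a.data.shape),
                                          _unbroadcast(g, b.data.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data
    return _make(data, (a, b), lambda g: (_unbroadcast(g * b.data, a.data.shape),
                                          _unbroadcast(g * a.data, b.data.shape)))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """a: (..., n, k) @ b: (k, m); the weight is always 2-D."""
    data = a.data @ b.data

    def backward(g):
        ga = g @ b.data.T
        a2 = a.data.reshape(-1, a.data.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        gb = a2.T @ g2
        return ga, gb

    return _make(data, (a, b), backward)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    orig = a.data.shape
    return _make(a.data.reshape(shape), (a,), lambda g: (g.reshape(orig),))


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),))


def mean(a: Tensor, axis: int | tuple[int, ...] | None = None,
         keepdims: bool = False) -> Tensor:
    data = a.data.mean(axis=axis, keepdims=keepdims)
    shape = a.data.shape
    if axis is None:
        count = a.data.size
        axes: tuple[int, ...] = tuple(range(a.data.ndim))
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        count = int(np.prod([shape[ax] for ax in axes]))

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes) if axes else g
        return (np.broadcast_to(g, shape) / count,)

    return _make(data, (a,), backward)


_SQRT2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(a: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = a.data
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    data = x * cdf

    def backward(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return (g * (cdf + x * pdf),)

    return _make(data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return ((g - dot) * s,)

    return _make(s, (a,), backward)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (x.shape[2] - kh) // stride + 1
    Wo = (x.shape[3] - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]          # B,C,Ho,Wo,kh,kw
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * kh * kw)
    return np.ascontiguousarray(cols), Ho, Wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """Standard 2-D convolution; x (B,C,H,W), w (O,C,kh,kw), b (O,)."""
    B, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    cols, Ho, Wo = _im2col(x.data, kh, kw, stride, pad)
    out = cols @ w.data.reshape(O, -1).T                      # B, HoWo, O
    if b is not None:
        out = out + b.data
    data = out.transpose(0, 2, 1).reshape(B, O, Ho, Wo)

    def backward(g):
        g2 = g.reshape(B, O, Ho * Wo).transpose(0, 2, 1)      # B, HoWo, O
        gw = np.tensordot(g2, cols, axes=([0, 1], [0, 1])).reshape(O, C, kh, kw)
        gcols = g2 @ w.data.reshape(O, -1)                    # B, HoWo, C*kh*kw
        gx = _col2im(gcols, (B, C, H, W), kh, kw, stride, pad, Ho, Wo)
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return _make(data, parents, backward)


def _col2im(gcols: np.ndarray, xshape, kh, kw, stride, pad, Ho, Wo) -> np.ndarray:
    B, C, H, W = xshape
    gx = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=gcols.dtype)
    g6 = gcols.reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += g6[:, :, :, :, i, j]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


def dwconv3x3(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Depthwise 3×3 convolution, stride 1, same padding; w (C,3,3)."""
    B, C, H, W = x.data.shape
    if w.data.shape != (C, 3, 3):
        raise ValueError(f"depthwise weight must be ({C},3,3), got {w.data.shape}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    data = np.zeros((B, C, H, W), dtype=x.data.dtype)
    for i in range(3):
        for j in range(3):
            data += w.data[:, i, j][None, :, None, None] * xp[:, :, i:i + H, j:j + W]
    if b is not None:
        data = data + b.data[None, :, None, None]

    def backward(g):
        gw = np.zeros_like(w.data)
        for i in range(3):
            for j in range(3):
                gw[:, i, j] = (g * xp[:, :, i:i + H, j:j + W]).sum(axis=(0, 2, 3))
        gp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                gp[:, :, i:i + H, j:j + W] += w.data[:, i, j][None, :, None, None] * g
        gx = gp[:, :, 1:-1, 1:-1]
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return _make(data, parents, backward)


def conv1x1(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Pointwise convolution; x (B,C,H,W), w (C,O), b (O,)."""
    B, C, H, W = x.data.shape
    if w.data.shape[0] != C:
        raise ValueError(f"channel mismatch: input {C}, weight {w.data.shape[0]}")
    O = w.data.shape[1]
    data = np.tensordot(x.data, w.data, axes=([1], [0])).transpose(0, 3, 1, 2)
    if b is not None:
        data = data + b.data[None, :, None, None]

    def backward(g):
        gx = np.tensordot(g, w.data, axes=([1], [1])).transpose(0, 3, 1, 2)
        gw = np.tensordot(x.data, g, axes=([0, 2, 3], [0, 2, 3]))
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return _make(data, parents, backward)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5,
                running: tuple[np.ndarray, np.ndarray] | None = None) -> Tensor:
    """Per-channel batch normalization over (B, H, W).

    With ``running=(mean, var)`` the supplied statistics are used (eval mode,
    no backprop through them); otherwise batch statistics are used and
    differentiated through.
    """
    B, C, H, W = x.data.shape
    if running is not None:
        mu, var = running
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

        def backward_eval(g):
            gx = g * (gamma.data * inv)[None, :, None, None]
            ggamma = (g * xhat).sum(axis=(0, 2, 3))
            gbeta = g.sum(axis=(0, 2, 3))
            return gx, ggamma, gbeta

        return _make(data, (x, gamma, beta), backward_eval)

    m = B * H * W
    mu = x.data.mean(axis=(0, 2, 3))
    var = x.data.var(axis=(0, 2, 3))
    inv = 1.0 / np.sqrt(var + eps)
    xc = x.data - mu[None, :, None, None]
    xhat = xc * inv[None, :, None, None]
    data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3))
        gbeta = g.sum(axis=(0, 2, 3))
        gxhat = g * gamma.data[None, :, None, None]
        s1 = gxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        gx = inv[None, :, None, None] / m * (m * gxhat - s1 - xhat * s2)
        return gx, ggamma, gbeta

    return _make(data, (x, gamma, beta), backward)


def rope(x: Tensor, positions: np.ndarray, base: float = 10000.0) -> Tensor:
    """Rotary positional embedding on token sequences x (..., N, D), D even.

    Adjacent element pairs (x_{2i}, x_{2i+1}) of the token at position m are
    rotated by the angle m * base^(-2i/D).  The backward pass rotates the
    incoming gradient by the opposite angle (rotations are orthogonal).
    """
    D = x.data.shape[-1]
    if D % 2:
        raise ValueError("rope needs an even feature dimension")
    cos, sin = _rope_tables(np.asarray(positions), D, base)
    cos = cos.astype(x.data.dtype)
    sin = sin.astype(x.data.dtype)
    data = _rope_apply(x.data, cos, sin)
    return _make(data, (x,), lambda g: (_rope_apply(g, cos, -sin),))


def _rope_tables(positions: np.ndarray, D: int, base: float):
    i = np.arange(D // 2)
    theta = base ** (-2.0 * i / D)                      # (D/2,)
    ang = positions[:, None] * theta[None, :]           # (N, D/2)
    return np.cos(ang), np.sin(ang)


def _rope_apply(x: np.ndarray, cos: np.ndarray, sin: np.ndarray) -> np.ndarray:
    even = x[..., 0::2]
    odd = x[..., 1::2]
    out = np.empty_like(x)
    out[..., 0::2] = even * cos - odd * sin
    out[..., 1::2] = even * sin + odd * cos
    return out


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return mean(mul(diff, diff))


# ---------------------------------------------------------------------------
# modules


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal layer container: tracks parameters and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = s.copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(_dtype)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = Parameter(_kaiming(rng, (n_in, n_out), n_in))
        self.b = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return matmul(x, self.w) + self.b


class Conv2d(Module):
    def __init__(self, n_in: int, n_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.w = Parameter(_kaiming(rng, (n_out, n_in, k, k), n_in * k * k))
        self.b = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class DWConv3x3(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.w = Parameter(_kaiming(rng, (channels, 3, 3), 9))
        self.b = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        return dwconv3x3(x, self.w, self.b)


class Conv1x1(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        w = np.zeros((n_in, n_out)) if zero_init else _kaiming(rng, (n_in, n_out), n_in)
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return conv1x1(x, self.w, self.b)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=_dtype)
        self.running_var = np.ones(channels, dtype=_dtype)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            return batchnorm2d(x, self.gamma, self.beta, self.eps)
        return batchnorm2d(x, self.gamma, self.beta, self.eps,
                           running=(self.running_mean, self.running_var))


class Adam:
    """Adam optimizer (bias-corrected first/second moments)."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        # moments kept in float64: g*g can overflow float32 range on the
        # steep early-training gradients of deep normalized stacks
        self.m = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]
        self.v = [np.zeros(p.data.shape, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
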