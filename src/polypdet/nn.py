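"""Minimal reverse-mode autodiff engine and neural-network layers on NumPy.

Everything the detector needs — 2-D convolution, batch normalisation, the
usual activations, pooling, nearest-neighbour upsampling, concatenation and
the element-wise algebra used by the loss — is implemented here as operations
on :class:`Tensor`, a thin wrapper around a ``float32`` ndarray that records
a backward closure.  ``Tensor.backward()`` runs reverse-mode accumulation in
topological order.

Convolutions are evaluated as a sum over kernel taps of BLAS ``tensordot``
calls rather than via an explicit im2col buffer, which keeps peak memory
proportional to the activations themselves.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "SGD",
    "concat",
    "sigmoid",
    "silu",
    "relu",
    "leaky_relu",
    "hardswish",
    "maxpool2d",
    "upsample_nearest2x",
    "mean_axis",
    "bce_with_logits",
]


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / float(other))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def sum(self):
        return tsum(self)

    def mean(self):
        return mul(tsum(self), 1.0 / self.data.size)

    def reshape(self, *shape):
        return reshape(self, shape)


class Parameter(Tensor):
    """A trainable tensor; ``decay`` marks it for weight decay."""

    __slots__ = ("decay",)

    def __init__(self, data, decay: bool = False):
        super().__init__(data, requires_grad=True)
        self.decay = decay


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _needs(*parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    p = float(p)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a, eps: float = 1e-12) -> Tensor:
    a = _wrap(a)
    safe = np.maximum(a.data, eps)
    out_data = np.log(safe)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g / safe)

    return _make(out_data, (a,), backward)


def sqrt(a, eps: float = 0.0) -> Tensor:
    a = _wrap(a)
    out_data = np.sqrt(a.data + eps)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * 0.5 / np.maximum(out_data, 1e-12))

    return _make(out_data, (a,), backward)


def arctan(a) -> Tensor:
    a = _wrap(a)
    out_data = np.arctan(a.data)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g / (1.0 + a.data ** 2))

    return _make(out_data, (a,), backward)


def clip(a, lo: float | None, hi: float | None) -> Tensor:
    """Clamp; gradient passes only through the un-clamped region."""
    a = _wrap(a)
    out_data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask *= (a.data >= lo)
    if hi is not None:
        mask *= (a.data <= hi)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * mask)

    return _make(out_data, (a,), backward)


def maximum(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = np.maximum(a.data, b.data)
    take_a = a.data >= b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * (~take_a), b.data.shape))

    return _make(out_data, (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = np.minimum(a.data, b.data)
    take_a = a.data <= b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * (~take_a), b.data.shape))

    return _make(out_data, (a, b), backward)


def tsum(a) -> Tensor:
    a = _wrap(a)
    out_data = np.array(a.data.sum(), dtype=np.float32)

    def backward(g):
        if a.requires_grad:
            a.accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))

    return _make(out_data, (a,), backward)


def mean_axis(a, axis: int, keepdims: bool = True) -> Tensor:
    a = _wrap(a)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.shape[axis]

    def backward(g):
        if a.requires_grad:
            gg = g if keepdims else np.expand_dims(g, axis)
            a.accumulate(np.broadcast_to(gg / n, a.data.shape).astype(np.float32))

    return _make(out_data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g.transpose(inv))

    return _make(out_data, (a,), backward)


def take(a, idx) -> Tensor:
    """Fancy-index ``a.data[idx]``; backward scatter-adds."""
    a = _wrap(a)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            if a.grad is None:
                a.grad = np.zeros_like(a.data)
            np.add.at(a.grad, idx, g)

    return _make(out_data, (a,), backward)


def stack(ts: Sequence[Tensor], axis: int = -1) -> Tensor:
    ts = [_wrap(t) for t in ts]
    out_data = np.stack([t.data for t in ts], axis=axis)

    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gi in zip(ts, parts):
            if t.requires_grad:
                t.accumulate(gi)

    return _make(out_data, ts, backward)


def concat(ts: Sequence[Tensor], axis: int = 1) -> Tensor:
    ts = [_wrap(t) for t in ts]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]

    def backward(g):
        splits = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, gi in zip(ts, splits):
            if t.requires_grad:
                t.accumulate(gi)

    return _make(out_data, ts, backward)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    e = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    s = _stable_sigmoid(a.data)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def silu(a) -> Tensor:
    a = _wrap(a)
    s = _stable_sigmoid(a.data)
    out_data = a.data * s

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * s * (1.0 + a.data * (1.0 - s)))

    return _make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def leaky_relu(a, slope: float = 0.1) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    factor = np.where(mask, 1.0, slope).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * factor)

    return _make(a.data * factor, (a,), backward)


def hardswish(a) -> Tensor:
    a = _wrap(a)
    inner = np.clip(a.data + 3.0, 0.0, 6.0)
    out_data = a.data * inner / 6.0
    deriv = np.where(a.data <= -3.0, 0.0,
                     np.where(a.data >= 3.0, 1.0, (2.0 * a.data + 3.0) / 6.0)
                     ).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a.accumulate(g * deriv)

    return _make(out_data, (a,), backward)


ACTIVATIONS = {
    "silu": silu,
    "relu": relu,
    "leaky_relu": leaky_relu,
    "hardswish": hardswish,
    "sigmoid": sigmoid,
    "none": lambda t: t,
}


# ---------------------------------------------------------------------------
# spatial ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution, NCHW layout, square kernel/stride/padding."""
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w}")
    s, p, d = stride, padding, dilation
    ho = (h + 2 * p - d * (kh - 1) - 1) // s + 1
    wo = (wd + 2 * p - d * (kw - 1) - 1) // s + 1
    if ho < 1 or wo < 1:
        raise ValueError("conv2d: output would be empty")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data

    out_data = np.zeros((n, cout, ho, wo), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            sl = xp[:, :, ki * d: ki * d + s * (ho - 1) + 1: s,
                    kj * d: kj * d + s * (wo - 1) + 1: s]
            # (n, cin, ho, wo) x (cout, cin) -> (n, cout, ho, wo)
            out_data += np.tensordot(sl, w.data[:, :, ki, kj],
                                     axes=([1], [1])).transpose(0, 3, 1, 2)
    if b is not None:
        out_data += b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        need_x = x.requires_grad
        need_w = w.requires_grad
        if not (need_x or need_w):
            return
        gxp = np.zeros_like(xp) if need_x else None
        gw = np.zeros_like(w.data) if need_w else None
        for ki in range(kh):
            for kj in range(kw):
                sl_idx = (slice(None), slice(None),
                          slice(ki * d, ki * d + s * (ho - 1) + 1, s),
                          slice(kj * d, kj * d + s * (wo - 1) + 1, s))
                if need_w:
                    sl = xp[sl_idx]
                    gw[:, :, ki, kj] = np.tensordot(g, sl, axes=([0, 2, 3], [0, 2, 3]))
                if need_x:
                    # (n, cout, ho, wo) x (cout, cin) -> (n, cin, ho, wo)
                    gx_part = np.tensordot(g, w.data[:, :, ki, kj],
                                           axes=([1], [0])).transpose(0, 3, 1, 2)
                    gxp[sl_idx] += gx_part
        if need_w:
            w.accumulate(gw)
        if need_x:
            x.accumulate(gxp[:, :, p: p + h, p: p + wd] if p else gxp)

    return _make(out_data, parents, backward)


def maxpool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    n, c, h, w = x.data.shape
    k, s, p = kernel, stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=-np.inf) if p else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - k) // s + 1
    wo = (wp - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::s, ::s]                       # (n, c, ho, wo, k, k)
    flat = win.reshape(n, c, ho, wo, k * k)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        oi, oj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        ri = oi[None, None] * s + arg // k
        rj = oj[None, None] * s + arg % k
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(gxp, (np.broadcast_to(ni, arg.shape),
                        np.broadcast_to(ci, arg.shape), ri, rj), g)
        x.accumulate(gxp[:, :, p: p + h, p: p + w] if p else gxp)

    return _make(out_data, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            x.accumulate(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return _make(out_data, (x,), backward)


def bce_with_logits(logits: Tensor, target: np.ndarray | Tensor,
                    weight: np.ndarray | None = None) -> Tensor:
    """Numerically stable per-element binary cross-entropy; returns the mean."""
    t = target.data if isinstance(target, Tensor) else _as_f32(target)
    z = logits.data
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if weight is not None:
        loss = loss * weight
    out_data = np.array(loss.mean(), dtype=np.float32)
    n = loss.size

    def backward(g):
        if logits.requires_grad:
            grad = (_stable_sigmoid(z) - t)
            if weight is not None:
                grad = grad * weight
            logits.accumulate(g * grad / n)

    return _make(out_data, (logits,), backward)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter discovery, train/eval mode, zeroing of grads."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterable["Module"]:
        def walk(v):
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    yield from walk(item)

        yield self
        for v in self.__dict__.values():
            yield from walk(v)

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    out.append(v)
        return out

    def count_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (BN stats)."""
        out: dict[str, np.ndarray] = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                if isinstance(v, Parameter):
                    out[f"m{i}.{k}"] = v.data
                elif isinstance(v, np.ndarray):
                    out[f"m{i}.{k}"] = v
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        if set(own) != set(arrays):
            raise ValueError("state mismatch: checkpoint does not fit this model")
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                key = f"m{i}.{k}"
                if key in arrays:
                    src = np.asarray(arrays[key])
                    dst_shape = v.data.shape if isinstance(v, Parameter) else v.shape
                    if src.shape != dst_shape:
                        raise ValueError(f"shape mismatch for {key}")
                    if isinstance(v, Parameter):
                        v.data = src.astype(np.float32)
                    else:
                        m.__dict__[k] = src.astype(np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int | None = None, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if padding is None:
            padding = dilation * (kernel - 1) // 2
        self.cin, self.cout = cin, cout
        self.kernel, self.stride, self.padding, self.dilation = kernel, stride, padding, dilation
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel * kernel
        bound = math.sqrt(2.0 / fan_in)       # He-style for the SiLU family
        self.weight = Parameter(rng.normal(0.0, bound, (cout, cin, kernel, kernel)),
                                decay=True)
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    """Per-channel batch normalisation.

    ``frozen=True`` switches the layer to its running statistics even in
    training mode (and stops updating them); the scale/shift parameters keep
    training.  Freezing late in training aligns the optimisation with
    inference-time behaviour, which matters at small batch sizes.
    """

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.channels = channels
        self.eps = float(eps)
        self.momentum = float(momentum)
        self.frozen = False
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        g, b = self.gamma, self.beta
        if self.training and not self.frozen:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(1, -1, 1, 1)) * inv_std.reshape(1, -1, 1, 1)
        out_data = g.data.reshape(1, -1, 1, 1) * xhat + b.data.reshape(1, -1, 1, 1)
        training = self.training and not self.frozen

        def backward(grad):
            if b.requires_grad:
                b.accumulate(grad.sum(axis=(0, 2, 3)))
            if g.requires_grad:
                g.accumulate((grad * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gs = grad * g.data.reshape(1, -1, 1, 1)
                if training:
                    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                    s1 = gs.sum(axis=(0, 2, 3), keepdims=True)
                    s2 = (gs * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    gx = (gs - s1 / n - xhat * s2 / n) * inv_std.reshape(1, -1, 1, 1)
                else:
                    gx = gs * inv_std.reshape(1, -1, 1, 1)
                x.accumulate(gx.astype(np.float32))

        return _make(out_data, (x, g, b), backward)


class SGD:
    """Stochastic gradient descent with momentum and optional weight decay.

    Decay applies only to parameters flagged ``decay`` (conv weights), mirroring
    the usual practice of excluding norm scales and biases.
    """

    def __init__(self, params: Sequence[Parameter], lr: float = 0.01,
                 momentum: float = 0.9, weight_decay: float = 0.0,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((p.grad ** 2).sum())
                                  for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= scale
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and getattr(p, "decay", False):
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
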