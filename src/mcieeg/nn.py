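"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the operations the package's
two classifiers need: broadcast arithmetic, batched matmul, 1-D and
depthwise convolutions, batch/layer normalization, softmax attention,
dropout, pooling and a fused softmax cross-entropy.  Gradients flow to
parameters *and* to inputs, which is what the expected-gradients
attribution estimator relies on.

Everything is deterministic given the generator handed to the stochastic
layers; there is no hidden global state.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Dense",
    "Conv1dSame",
    "BatchNorm",
    "LayerNorm",
    "Dropout",
    "relu",
    "elu",
    "softmax",
    "mean_axis",
    "softmax_cross_entropy",
    "Adam",
]


class Tensor:
    """Node of the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = _prev
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ----------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.asarray(grad, dtype=float)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- operators ----------------------------------------------------------

    def __add__(self, other):
        other = _wrap(other)

        def bw(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, _prev=(self, other), _backward=bw)

    def __mul__(self, other):
        other = _wrap(other)

        def bw(g):
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, _prev=(self, other), _backward=bw)

    def __neg__(self):
        def bw(g):
            _accum(self, -g)

        return Tensor(-self.data, _prev=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-_wrap(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _wrap(other)
        out = self.data @ other.data

        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            _accum(self, _unbroadcast(ga, self.data.shape))
            _accum(other, _unbroadcast(gb, other.data.shape))

        return Tensor(out, _prev=(self, other), _backward=bw)

    def reshape(self, *shape):
        def bw(g):
            _accum(self, g.reshape(self.data.shape))

        return Tensor(self.data.reshape(*shape), _prev=(self,), _backward=bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            _accum(self, g.transpose(*inv))

        return Tensor(self.data.transpose(*axes), _prev=(self,), _backward=bw)

    def slice_axis1(self, start, stop):
        """x[:, start:stop] with zero-padded gradient."""

        def bw(g):
            full = np.zeros_like(self.data)
            full[:, start:stop] = g
            _accum(self, full)

        return Tensor(self.data[:, start:stop], _prev=(self,), _backward=bw)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g):
    if t.requires_grad and t.grad is not None:
        t.grad += g


def _unbroadcast(g, shape):
    """Sum gradient over broadcast dimensions back to the original shape."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# functional ops


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        _accum(x, g * mask)

    return Tensor(x.data * mask, _prev=(x,), _backward=bw)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    out = np.where(pos, x.data, alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0))

    def bw(g):
        _accum(x, g * np.where(pos, 1.0, out + alpha))

    return Tensor(out, _prev=(x,), _backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        _accum(x, y * (g - dot))

    return Tensor(y, _prev=(x,), _backward=bw)


def mean_axis(x: Tensor, axis: int) -> Tensor:
    n = x.data.shape[axis]

    def bw(g):
        _accum(x, np.repeat(np.expand_dims(g / n, axis), n, axis=axis))

    return Tensor(x.data.mean(axis=axis), _prev=(x,), _backward=bw)


def sum_all(x: Tensor) -> Tensor:
    def bw(g):
        _accum(x, np.full_like(x.data, g))

    return Tensor(x.data.sum(), _prev=(x,), _backward=bw)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy with fused softmax gradient."""
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = len(labels)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))

    def bw(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        _accum(logits, g * grad / n)

    return Tensor(loss, _prev=(logits,), _backward=bw)


def avg_pool_axis1(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping mean pooling along axis 1 (length must divide)."""
    b = x.data.shape[0]
    t = x.data.shape[1]
    if t % factor:
        raise ValueError("pool factor must divide the axis length")
    rest = x.data.shape[2:]
    out = x.data.reshape(b, t // factor, factor, *rest).mean(axis=2)

    def bw(g):
        gg = np.repeat(g[:, :, None], factor, axis=2) / factor
        _accum(x, gg.reshape(x.data.shape))

    return Tensor(out, _prev=(x,), _backward=bw)


def conv1d_same(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """1-D convolution with same-padding.

    ``x``: (batch, T, Cin); ``w``: (K, Cin, Cout), K odd; output
    (batch, T, Cout).  Implemented as a sum over kernel taps of shifted
    matmuls, which keeps both directions exact and fast for small K.
    """
    K = w.data.shape[0]
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    T = x.data.shape[1]
    out = np.zeros(x.data.shape[:2] + (w.data.shape[2],))
    for k in range(K):
        out += xp[:, k : k + T, :] @ w.data[k]
    if b is not None:
        out += b.data

    def bw(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for k in range(K):
            gxp[:, k : k + T, :] += g @ w.data[k].T
            gw[k] = np.einsum("bti,bto->io", xp[:, k : k + T, :], g)
        _accum(x, gxp[:, pad : pad + T, :])
        _accum(w, gw)
        if b is not None:
            _accum(b, g.sum(axis=(0, 1)))

    prev = (x, w) if b is None else (x, w, b)
    return Tensor(out, _prev=prev, _backward=bw)


def depthwise_spatial(x: Tensor, w: Tensor) -> Tensor:
    """Collapse the channel axis with per-map weights (EEGNet-style).

    ``x``: (batch, C, T, F); ``w``: (C, F, D); output (batch, T, F, D)
    where out[b,t,f,d] = sum_c x[b,c,t,f] * w[c,f,d].
    """
    out = np.einsum("bctf,cfd->btfd", x.data, w.data)

    def bw(g):
        _accum(x, np.einsum("btfd,cfd->bctf", g, w.data))
        _accum(w, np.einsum("bctf,btfd->cfd", x.data, g))

    return Tensor(out, _prev=(x, w), _backward=bw)


def depthwise_temporal(x: Tensor, w: Tensor) -> Tensor:
    """Per-map temporal convolution with same-padding.

    ``x``: (batch, T, M); ``w``: (K, M), K odd; output (batch, T, M).
    """
    K = w.data.shape[0]
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    T = x.data.shape[1]
    out = np.zeros_like(x.data)
    for k in range(K):
        out += xp[:, k : k + T, :] * w.data[k]

    def bw(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for k in range(K):
            gxp[:, k : k + T, :] += g * w.data[k]
            gw[k] = (xp[:, k : k + T, :] * g).sum(axis=(0, 1))
        _accum(x, gxp[:, pad : pad + T, :])
        _accum(w, gw)

    return Tensor(out, _prev=(x, w), _backward=bw)


# ---------------------------------------------------------------------------
# modules


class Module:
    """Base class: parameter discovery + train/eval mode propagation."""

    def parameters(self) -> list[Parameter]:
        out = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            m.training = getattr(m, "training", True)
            m.training = flag

    def state_dict(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm):
                state.append(m.running_mean.copy())
                state.append(m.running_var.copy())
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[: len(params)]):
            p.data = s.copy()
        i = len(params)
        for m in self.modules():
            if isinstance(m, BatchNorm):
                m.running_mean = state[i].copy()
                m.running_var = state[i + 1].copy()
                i += 2


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.w = Parameter(rng.normal(0.0, scale, (n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1dSame(Module):
    def __init__(self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for same-padding")
        scale = np.sqrt(2.0 / (kernel * c_in + c_out))
        self.w = Parameter(rng.normal(0.0, scale, (kernel, c_in, c_out)))
        self.b = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.w, self.b)


class BatchNorm(Module):
    """Normalizes the trailing feature axis over all leading axes."""

    def __init__(self, n_feat: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_feat))
        self.beta = Parameter(np.zeros(n_feat))
        self.running_mean = np.zeros(n_feat)
        self.running_var = np.ones(n_feat)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.data.ndim - 1))
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat_data = (x.data - mu) * inv
        n = x.data.size // x.data.shape[-1]

        def bw(g):
            # gradient of the (training-mode) normalization
            gg = g * self.gamma.data
            if self.training:
                dvar = (gg * (x.data - mu)).sum(axis=axes) * (-0.5) * inv**3
                dmu = (-gg * inv).sum(axis=axes) + dvar * (-2.0 / n) * (
                    x.data - mu
                ).sum(axis=axes)
                gx = gg * inv + dvar * 2.0 * (x.data - mu) / n + dmu / n
            else:
                gx = gg * inv
            _accum(x, gx)
            _accum(self.gamma, (g * xhat_data).sum(axis=axes))
            _accum(self.beta, g.sum(axis=axes))

        out = Tensor(
            xhat_data * self.gamma.data + self.beta.data,
            _prev=(x, self.gamma, self.beta),
            _backward=bw,
        )
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.data.mean(axis=-1, keepdims=True)
        var = x.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        d = x.data.shape[-1]

        def bw(g):
            gg = g * self.gamma.data
            gx = (
                gg
                - gg.mean(axis=-1, keepdims=True)
                - xhat * (gg * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            _accum(x, gx)
            red = tuple(range(g.ndim - 1))
            _accum(self.gamma, (g * xhat).sum(axis=red))
            _accum(self.beta, g.sum(axis=red))

        return Tensor(
            xhat * self.gamma.data + self.beta.data,
            _prev=(x, self.gamma, self.beta),
            _backward=bw,
        )


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)

        def bw(g):
            _accum(x, g * mask)

        return Tensor(x.data * mask, _prev=(x,), _backward=bw)


class Adam:
    """Adam with optional per-epoch exponential learning-rate decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay_l2: float = 0.0):
        self.params = params
        self.lr0 = lr
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.l2 = weight_decay_l2
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def set_epoch(self, epoch: int, decay: float = 0.96) -> None:
        self.lr = self.lr0 * decay**epoch

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            if self.l2 and p.data.ndim > 1:  # weights only, not biases/gains
                g = g + 2.0 * self.l2 * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
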