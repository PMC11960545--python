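"""A small reverse-mode automatic-differentiation engine on numpy.

Implements exactly the operations the imputation model needs: dense and 1-D
convolutional layers, non-overlapping max pooling, batch/layer norm,
multi-head self-attention with residual connections, dropout, and Adam.
Gradients are exact (checked against central finite differences in the test
suite) and every stochastic choice (initialization, dropout masks) draws
from an explicit numpy Generator, so training is bit-reproducible.

Array layout convention is channels-last: sequence tensors are
(batch, length, channels).
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from typing import Callable, Iterable, Sequence

import numpy as np

_grad_enabled = True

# float32 is the working precision (single-threaded BLAS is deterministic
# either way); switchable to float64 for finite-difference gradient checks
DEFAULT_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DEFAULT_DTYPE
    DEFAULT_DTYPE = np.dtype(dtype).type


@contextmanager
def default_dtype(dtype):
    global DEFAULT_DTYPE
    prev = DEFAULT_DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(prev)


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DEFAULT_DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward: Callable | None = None

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ----------------------------------------------------

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
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def __getitem__(self, key):
        return getitem(self, key)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward(out)
    return out


def _accum(p: Tensor, g: np.ndarray) -> None:
    if not p.requires_grad:
        return
    if p.grad is None:
        p.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        p.grad = p.grad + g


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def bw(out):
        def run(g):
            _accum(a, _unbroadcast(g, a.data.shape))
            _accum(b, _unbroadcast(g, b.data.shape))
        return run

    return _make(data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def bw(out):
        def run(g):
            _accum(a, _unbroadcast(g * b.data, a.data.shape))
            _accum(b, _unbroadcast(g * a.data, b.data.shape))
        return run

    return _make(data, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data / b.data

    def bw(out):
        def run(g):
            _accum(a, _unbroadcast(g / b.data, a.data.shape))
            _accum(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))
        return run

    return _make(data, (a, b), bw)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def bw(out):
        def run(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            _accum(a, _unbroadcast(ga, a.data.shape))
            _accum(b, _unbroadcast(gb, b.data.shape))
        return run

    return _make(data, (a, b), bw)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def bw(out):
        def run(g):
            _accum(a, g * (a.data > 0))
        return run

    return _make(data, (a,), bw)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def bw(out):
        def run(g):
            _accum(a, g * data * (1.0 - data))
        return run

    return _make(data, (a,), bw)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def bw(out):
        def run(g):
            _accum(a, g / a.data)
        return run

    return _make(data, (a,), bw)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** exponent

    def bw(out):
        def run(g):
            _accum(a, g * exponent * a.data ** (exponent - 1.0))
        return run

    return _make(data, (a,), bw)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(out):
        def run(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(gg, a.data.shape).copy())
        return run

    return _make(data, (a,), bw)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def bw(out):
        def run(g):
            _accum(a, g.reshape(a.data.shape))
        return run

    return _make(data, (a,), bw)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bw(out):
        def run(g):
            _accum(a, g.transpose(inv))
        return run

    return _make(data, (a,), bw)


def getitem(a, key) -> Tensor:
    a = _as_tensor(a)
    data = a.data[key]

    def bw(out):
        def run(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            _accum(a, full)
        return run

    return _make(data, (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(out):
        def run(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                _accum(t, piece)
        return run

    return _make(data, tuple(tensors), bw)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def bw(out):
        def run(g):
            gy = g * data
            _accum(a, gy - data * gy.sum(axis=axis, keepdims=True))
        return run

    return _make(data, (a,), bw)


def conv1d(x, w, b, padding: str = "same") -> Tensor:
    """1-D convolution, channels-last.

    x: (B, L, Cin); w: (k, Cin, Cout); b: (Cout,).  'same' padding keeps the
    length; 'valid' yields L - k + 1 positions.
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    k, cin, cout = w.data.shape
    if padding == "same":
        pl, pr = (k - 1) // 2, k // 2
    elif padding == "valid":
        pl = pr = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    bsz, lp, _ = xp.shape
    lout = lp - k + 1
    # (B, Lout, Cin, k) -> (B, Lout, k, Cin) -> (B, Lout, k*Cin)
    col = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    col = np.ascontiguousarray(col.transpose(0, 1, 3, 2)).reshape(bsz, lout, k * cin)
    wm = w.data.reshape(k * cin, cout)
    data = col @ wm + b.data

    def bw(out):
        def run(g):
            gflat = g.reshape(-1, cout)
            _accum(w, (col.reshape(-1, k * cin).T @ gflat).reshape(k, cin, cout))
            _accum(b, gflat.sum(axis=0))
            if x.requires_grad:
                gcol = (g @ wm.T).reshape(bsz, lout, k, cin)
                gxp = np.zeros_like(xp)
                for i in range(k):
                    gxp[:, i:i + lout, :] += gcol[:, :, i, :]
                _accum(x, gxp[:, pl:pl + x.data.shape[1], :])
        return run

    return _make(data, (x, w, b), bw)


def maxpool1d(x, step: int) -> Tensor:
    """Non-overlapping max pooling along the length axis; the tail shorter
    than ``step`` is dropped."""
    x = _as_tensor(x)
    bsz, length, ch = x.data.shape
    lt = length // step
    xr = x.data[:, :lt * step, :].reshape(bsz, lt, step, ch)
    idx = xr.argmax(axis=2)
    data = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def bw(out):
        def run(g):
            gr = np.zeros((bsz, lt, step, ch))
            np.put_along_axis(gr, idx[:, :, None, :], g[:, :, None, :], axis=2)
            gx = np.zeros_like(x.data)
            gx[:, :lt * step, :] = gr.reshape(bsz, lt * step, ch)
            _accum(x, gx)
        return run

    return _make(data, (x,), bw)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    """Minimal module base: parameter traversal, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def children(self) -> Iterable["Module"]:
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list:
        params = []
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                params.append(value)
        for child in self.children():
            params.extend(child.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> dict:
        out = {}
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                out[prefix + name] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(prefix + name + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{prefix}{name}.{i}."))
        return out

    def buffers(self, prefix: str = "") -> dict:
        """Non-learned state (running statistics)."""
        out = {}
        for name, value in vars(self).items():
            if isinstance(value, Module):
                out.update(value.buffers(prefix + name + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.buffers(f"{prefix}{name}.{i}."))
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                out[prefix + name] = value
        return out

    def state_dict(self) -> dict:
        state = {k: v.data.copy() for k, v in self.named_parameters().items()}
        state.update({"buffer:" + k: v.copy() for k, v in self.buffers().items()})
        return state

    def load_state_dict(self, state: dict, strict: bool = True) -> list:
        """Load matching-shape entries; returns the names skipped."""
        params = self.named_parameters()
        skipped = []
        for key, value in state.items():
            if key.startswith("buffer:"):
                name = key[len("buffer:"):]
                self._set_buffer(name, value)
                continue
            if key in params and params[key].data.shape == value.shape:
                params[key].data = value.copy()
            else:
                skipped.append(key)
        if strict and skipped:
            raise KeyError(f"state entries not loadable: {skipped}")
        return skipped

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        if hasattr(obj, parts[-1]):
            setattr(obj, parts[-1], value.copy())

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for child in self.children():
            child.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_glorot(rng, n_in, n_out, (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator, padding: str = "same"):
        super().__init__()
        fan_in = kernel_size * c_in
        self.weight = Parameter(_glorot(rng, fan_in, c_out,
                                        (kernel_size, c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.padding)


class Dropout(Module):
    """Inverted dropout; draws masks from the shared model generator."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError(f"dropout rate must be in [0,1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return mul(x, Tensor(mask))


class BatchNorm(Module):
    """Per-channel normalization over batch (and length) axes, channels-last."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DEFAULT_DTYPE)
        self.running_var = np.ones(channels, dtype=DEFAULT_DTYPE)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mean = tmean(x, axis=axes, keepdims=True)
            var = tmean(power(x - mean, 2.0), axis=axes, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            xhat = (x - mean) * power(var + self.eps, -0.5)
        else:
            xhat = ((x - self.running_mean)
                    * (self.running_var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mean = tmean(x, axis=-1, keepdims=True)
        var = tmean(power(x - mean, 2.0), axis=-1, keepdims=True)
        return (x - mean) * power(var + self.eps, -0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"model_dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        bsz, length, dim = x.shape
        h, hd = self.n_heads, self.head_dim

        def split(t):  # (B, T, D) -> (B, H, T, hd)
            return transpose(reshape(t, (bsz, length, h, hd)), (0, 2, 1, 3))

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = mul(matmul(q, transpose(k, (0, 1, 3, 2))), 1.0 / math.sqrt(hd))
        attn = softmax(scores, axis=-1)
        ctx = matmul(attn, v)  # (B, H, T, hd)
        ctx = reshape(transpose(ctx, (0, 2, 1, 3)), (bsz, length, dim))
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: residual self-attention then residual FFN,
    each followed by layer norm, with dropout on each sub-layer output."""

    def __init__(self, dim: int, n_heads: int, ffn_dim: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ffn_dim, rng)
        self.ff2 = Linear(ffn_dim, dim, rng)
        self.norm2 = LayerNorm(dim)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop1(self.attn(x)))
        x = self.norm2(x + self.drop2(self.ff2(relu(self.ff1(x)))))
        return x


class TransformerEncoder(Module):
    def __init__(self, n_layers: int, dim: int, n_heads: int, ffn_dim: int,
                 dropout: float, n_positions: int, rng: np.random.Generator,
                 positional: bool = True):
        super().__init__()
        self.layers = [TransformerEncoderLayer(dim, n_heads, ffn_dim, dropout, rng)
                       for _ in range(n_layers)]
        self.pos = (Parameter(rng.normal(0.0, 0.02, size=(n_positions, dim)))
                    if positional else None)

    def __call__(self, x: Tensor) -> Tensor:
        if self.pos is not None:
            x = x + self.pos
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
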