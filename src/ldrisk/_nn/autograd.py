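"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the model zoo needs: broadcasted
arithmetic, matrix products, elementwise nonlinearities, reductions,
reshaping, concatenation, 1-D/2-D cross-correlation and max pooling.
Gradients are accumulated by topological-sort backpropagation from a
scalar loss. Nodes whose inputs do not require gradients build no graph,
so inference passes allocate nothing beyond the forward arrays.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "tanh",
    "sigmoid",
    "exp",
    "log",
    "sqrt",
    "softmax",
    "concat",
    "stack",
    "dropout",
    "conv1d",
    "conv2d",
    "maxpool1d",
    "maxpool2d",
]


_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction, e.g. for inference passes."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` along axes numpy broadcast over."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "_parents", "_grad_fn", "requires_grad")

    def __init__(self, data, parents=(), grad_fn=None, requires_grad=False):
        self.data = np.asarray(data)
        self._parents = parents
        self._grad_fn = grad_fn
        self.requires_grad = requires_grad or (
            _grad_enabled and any(p.requires_grad for p in parents))
        if not self.requires_grad:
            # dead branch: drop references so the graph can be collected
            self._parents = ()
            self._grad_fn = None
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS; graphs from long LSTM rollouts overflow recursion
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(stack.pop())
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._grad_fn is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._grad_fn(node.grad)):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy() if g.base is not None else g
                else:
                    parent.grad += g

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __neg__(self):
        return mul(self, as_tensor(np.array(-1.0, dtype=self.data.dtype)))

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __pow__(self, exponent):
        return power(self, float(exponent))

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


# -- arithmetic ---------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def grad_fn(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor(out, (a, b), grad_fn)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def grad_fn(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out, (a, b), grad_fn)


def power(a: Tensor, exponent: float) -> Tensor:
    out = a.data ** exponent

    def grad_fn(g):
        return (g * exponent * a.data ** (exponent - 1.0),)

    return Tensor(out, (a,), grad_fn)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data

    def grad_fn(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

    return Tensor(out, (a, b), grad_fn)


# -- elementwise nonlinearities ----------------------------------------

def relu(a: Tensor) -> Tensor:
    out = np.maximum(a.data, 0.0)

    def grad_fn(g):
        return (g * (a.data > 0.0),)

    return Tensor(out, (a,), grad_fn)


def tanh(a: Tensor) -> Tensor:
    out = np.tanh(a.data)

    def grad_fn(g):
        return (g * (1.0 - out * out),)

    return Tensor(out, (a,), grad_fn)


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.data))

    def grad_fn(g):
        return (g * out * (1.0 - out),)

    return Tensor(out, (a,), grad_fn)


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)

    def grad_fn(g):
        return (g * out,)

    return Tensor(out, (a,), grad_fn)


def log(a: Tensor) -> Tensor:
    out = np.log(a.data)

    def grad_fn(g):
        return (g / a.data,)

    return Tensor(out, (a,), grad_fn)


def sqrt(a: Tensor) -> Tensor:
    out = np.sqrt(a.data)

    def grad_fn(g):
        return (g * 0.5 / out,)

    return Tensor(out, (a,), grad_fn)


# -- reductions / shape ------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def grad_fn(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g2, a.data.shape).copy(),)

    return Tensor(out, (a,), grad_fn)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)])
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    out = a.data.reshape(shape)

    def grad_fn(g):
        return (g.reshape(a.data.shape),)

    return Tensor(out, (a,), grad_fn)


def transpose(a: Tensor, axes) -> Tensor:
    out = a.data.transpose(axes)
    inv = np.argsort(axes)

    def grad_fn(g):
        return (g.transpose(inv),)

    return Tensor(out, (a,), grad_fn)


def _is_basic_index(key) -> bool:
    parts = key if isinstance(key, tuple) else (key,)
    return all(isinstance(k, (int, np.integer, slice)) or k is None
               or k is Ellipsis for k in parts)


def getitem(a: Tensor, key) -> Tensor:
    out = a.data[key]
    basic = _is_basic_index(key)  # basic slices never alias, so += is exact

    def grad_fn(g):
        full = np.zeros_like(a.data)
        if basic:
            full[key] += g
        else:
            np.add.at(full, key, g)
        return (full,)

    return Tensor(out, (a,), grad_fn)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, tuple(tensors), grad_fn)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def grad_fn(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor(out, tuple(tensors), grad_fn)


def softmax(a: Tensor, axis=-1) -> Tensor:
    shift = Tensor(a.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = exp(a - shift)
    return e / e.sum(axis=axis, keepdims=True)


def dropout(a: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; the identity outside of training."""
    if not training or rate <= 0.0:
        return a
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, Tensor(mask.astype(a.data.dtype)))


# -- convolution and pooling -------------------------------------------

def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid cross-correlation; x (N, L, Cin), w (K, Cin, Cout), b (Cout,)."""
    K = w.data.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=1)
    # windows: (N, Lout, Cin, K)
    out = np.einsum("nlck,kco->nlo", windows, w.data, optimize=True) + b.data

    def grad_fn(g):
        gw = np.einsum("nlck,nlo->kco", windows, g, optimize=True)
        gb = g.sum(axis=(0, 1))
        gx = np.zeros_like(x.data)
        Lout = g.shape[1]
        for k in range(K):
            gx[:, k:k + Lout, :] += np.einsum(
                "nlo,co->nlc", g, w.data[k], optimize=True)
        return gx, gw, gb

    return Tensor(out, (x, w, b), grad_fn)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid cross-correlation; x (N, H, W, Cin), w (Kh, Kw, Cin, Cout)."""
    Kh, Kw = w.data.shape[:2]
    windows = np.lib.stride_tricks.sliding_window_view(x.data, (Kh, Kw), axis=(1, 2))
    # windows: (N, Ho, Wo, Cin, Kh, Kw)
    out = np.einsum("nhwcij,ijco->nhwo", windows, w.data, optimize=True) + b.data

    def grad_fn(g):
        gw = np.einsum("nhwcij,nhwo->ijco", windows, g, optimize=True)
        gb = g.sum(axis=(0, 1, 2))
        gx = np.zeros_like(x.data)
        Ho, Wo = g.shape[1:3]
        for i in range(Kh):
            for j in range(Kw):
                gx[:, i:i + Ho, j:j + Wo, :] += np.einsum(
                    "nhwo,co->nhwc", g, w.data[i, j], optimize=True)
        return gx, gw, gb

    return Tensor(out, (x, w, b), grad_fn)


def maxpool1d(x: Tensor, size: int) -> Tensor:
    """Non-overlapping max pooling over axis 1; trailing remainder dropped."""
    N, L, C = x.data.shape
    Lo = L // size
    trimmed = x.data[:, :Lo * size, :].reshape(N, Lo, size, C)
    idx = trimmed.argmax(axis=2)
    out = np.take_along_axis(trimmed, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def grad_fn(g):
        gt = np.zeros((N, Lo, size, C), dtype=x.data.dtype)
        np.put_along_axis(gt, idx[:, :, None, :], g[:, :, None, :], axis=2)
        gx = np.zeros_like(x.data)
        gx[:, :Lo * size, :] = gt.reshape(N, Lo * size, C)
        return (gx,)

    return Tensor(out, (x,), grad_fn)


def maxpool2d(x: Tensor, size: int) -> Tensor:
    """Non-overlapping size×size max pooling over axes 1, 2."""
    N, H, W, C = x.data.shape
    Ho, Wo = H // size, W // size
    t = x.data[:, :Ho * size, :Wo * size, :].reshape(N, Ho, size, Wo, size, C)
    t = t.transpose(0, 1, 3, 2, 4, 5).reshape(N, Ho, Wo, size * size, C)
    idx = t.argmax(axis=3)
    out = np.take_along_axis(t, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def grad_fn(g):
        gt = np.zeros((N, Ho, Wo, size * size, C), dtype=x.data.dtype)
        np.put_along_axis(gt, idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        gt = gt.reshape(N, Ho, Wo, size, size, C).transpose(0, 1, 3, 2, 4, 5)
        gx = np.zeros_like(x.data)
        gx[:, :Ho * size, :Wo * size, :] = gt.reshape(N, Ho * size, Wo * size, C)
        return (gx,)

    return Tensor(out, (x,), grad_fn)
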