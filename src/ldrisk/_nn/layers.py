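"""Neural-network layers on top of the autograd engine.

Initialisation follows the Glorot uniform scheme from a caller-supplied
``numpy.random.Generator`` so builds are bit-reproducible under a seed.
Every layer exposes ``parameters()`` and ``__call__``; recurrent layers
consume and produce lists of per-timestep tensors to keep the graph flat.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor

DTYPE = np.float32


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng, activation=None):
        self.w = Parameter(glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Parameter(np.zeros(n_out, dtype=DTYPE))
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w + self.b
        return self.activation(y) if self.activation else y

    def parameters(self):
        return [self.w, self.b]


class Conv1D(Layer):
    def __init__(self, n_in: int, n_filters: int, kernel: int, rng,
                 activation=ag.relu):
        fan_in, fan_out = kernel * n_in, kernel * n_filters
        self.w = Parameter(glorot(rng, (kernel, n_in, n_filters), fan_in, fan_out))
        self.b = Parameter(np.zeros(n_filters, dtype=DTYPE))
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = ag.conv1d(x, self.w, self.b)
        return self.activation(y) if self.activation else y

    def parameters(self):
        return [self.w, self.b]


class Conv2D(Layer):
    def __init__(self, n_in: int, n_filters: int, kernel: int, rng,
                 activation=ag.relu):
        fan_in, fan_out = kernel * kernel * n_in, kernel * kernel * n_filters
        self.w = Parameter(
            glorot(rng, (kernel, kernel, n_in, n_filters), fan_in, fan_out))
        self.b = Parameter(np.zeros(n_filters, dtype=DTYPE))
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = ag.conv2d(x, self.w, self.b)
        return self.activation(y) if self.activation else y

    def parameters(self):
        return [self.w, self.b]


class LSTMLayer(Layer):
    """Single LSTM layer over a list of (batch, n_in) timestep tensors."""

    def __init__(self, n_in: int, n_units: int, rng):
        self.n_units = n_units
        # combined gate weights, gate order: input, forget, cell, output
        self.wx = Parameter(glorot(rng, (n_in, 4 * n_units), n_in, 4 * n_units))
        self.wh = Parameter(
            glorot(rng, (n_units, 4 * n_units), n_units, 4 * n_units))
        b = np.zeros(4 * n_units, dtype=DTYPE)
        b[n_units:2 * n_units] = 1.0  # forget-gate bias at 1, the usual default
        self.b = Parameter(b)

    def __call__(self, xs: list[Tensor], reverse: bool = False) -> list[Tensor]:
        n = self.n_units
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, n), dtype=DTYPE))
        c = Tensor(np.zeros((batch, n), dtype=DTYPE))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out: list[Tensor | None] = [None] * len(xs)
        for t in order:
            gates = xs[t] @ self.wx + h @ self.wh + self.b
            i = ag.sigmoid(gates[:, :n])
            f = ag.sigmoid(gates[:, n:2 * n])
            g = ag.tanh(gates[:, 2 * n:3 * n])
            o = ag.sigmoid(gates[:, 3 * n:])
            c = f * c + i * g
            h = o * ag.tanh(c)
            out[t] = h
        return out

    def parameters(self):
        return [self.wx, self.wh, self.b]


class BiLSTMLayer(Layer):
    """Forward and backward LSTM passes, outputs concatenated per step."""

    def __init__(self, n_in: int, n_units: int, rng):
        self.fwd = LSTMLayer(n_in, n_units, rng)
        self.bwd = LSTMLayer(n_in, n_units, rng)

    def __call__(self, xs: list[Tensor]) -> list[Tensor]:
        hf = self.fwd(xs)
        hb = self.bwd(xs, reverse=True)
        return [ag.concat([f, b], axis=1) for f, b in zip(hf, hb)]

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()


class LayerNorm(Layer):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim, dtype=DTYPE))
        self.beta = Parameter(np.zeros(dim, dtype=DTYPE))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ag.sqrt(var + self.eps) * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class MultiHeadAttention(Layer):
    """Scaled dot-product self-attention; input (batch, tokens, d_model).

    Each head projects to its own ``key_dim`` (default d_model // n_heads,
    at least 1), so the model width need not be divisible by the head
    count; the output projection maps n_heads * key_dim back to d_model.
    """

    def __init__(self, d_model: int, n_heads: int, rng, key_dim: int | None = None):
        self.n_heads = n_heads
        self.d_head = key_dim if key_dim is not None else max(1, d_model // n_heads)
        inner = n_heads * self.d_head
        self.wq = Parameter(glorot(rng, (d_model, inner), d_model, inner))
        self.wk = Parameter(glorot(rng, (d_model, inner), d_model, inner))
        self.wv = Parameter(glorot(rng, (d_model, inner), d_model, inner))
        self.wo = Parameter(glorot(rng, (inner, d_model), inner, d_model))

    def _split(self, x: Tensor) -> Tensor:
        n, t, _ = x.shape
        return x.reshape(n, t, self.n_heads, self.d_head).transpose((0, 2, 1, 3))

    def __call__(self, x: Tensor) -> Tensor:
        n, t, _ = x.shape
        q, k, v = self._split(x @ self.wq), self._split(x @ self.wk), \
            self._split(x @ self.wv)
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / math.sqrt(self.d_head))
        attn = ag.softmax(scores, axis=-1)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(
            n, t, self.n_heads * self.d_head)
        return ctx @ self.wo

    def parameters(self):
        return [self.wq, self.wk, self.wv, self.wo]


def positional_encoding(n_tokens: int, d_model: int) -> np.ndarray:
    """Sinusoidal position code, shape (n_tokens, d_model)."""
    pos = np.arange(n_tokens, dtype=np.float64)[:, None]
    i = np.arange(d_model, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2.0 * (i // 2) / d_model)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe.astype(DTYPE)
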