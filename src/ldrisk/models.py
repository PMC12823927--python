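"""Model zoo: six deep model families for genetic risk prediction.

Each family comes in two input modes. In *individual* mode the model maps
one sample's p standardized dosages to a single trait prediction. In
*summary* mode the model consumes an LD summary of the region instead —
the upper triangle (DNN), the full matrix as a feature sequence (LSTM,
BiLSTM), or diagonal blocks (CNN, transformer) — and emits one output per
training sample, O_1..O_{n_tr}, which are fitted jointly against the
training phenotypes.

Architectures are declared as :class:`ArchitectureSpec` values; the named
presets reproduce the benchmark configurations exactly (layer widths,
kernel sizes, dropout placement, attention heads). Output layers are
always linear; dropout is active only during fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._nn import autograd as ag
from ._nn.autograd import Tensor
from ._nn.layers import (DTYPE, BiLSTMLayer, Conv1D, Conv2D, Dense, LayerNorm,
                         LSTMLayer, MultiHeadAttention, positional_encoding)
from .ld import LDBlockSet, LDMatrix, window_slices

__all__ = ["ArchitectureSpec", "PredictorModel", "build_model", "predict",
           "architecture", "PRESETS"]

FAMILIES = ("dnn", "cnn1d", "cnn2d", "lstm", "bilstm", "transformer")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one model family instance."""

    family: str
    input_mode: str = "individual"
    layer_plan: tuple = ()
    output_dim: int = 1
    activation: str = "relu"
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.input_mode not in ("individual", "summary"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        if not self.layer_plan:
            raise ValueError("layer_plan must be non-empty")


def _act(name: str):
    return {"relu": ag.relu, "tanh": ag.tanh, "sigmoid": ag.sigmoid}[name]


# ---------------------------------------------------------------------
# family networks


class _DNNNet:
    def __init__(self, spec, input_dim, rng):
        act = _act(spec.activation)
        self.steps = []  # ("dense", layer) | ("dropout", rate)
        d = input_dim
        for entry in spec.layer_plan:
            if entry["type"] == "dense":
                self.steps.append(("dense", Dense(d, entry["units"], rng, act)))
                d = entry["units"]
            elif entry["type"] == "dropout":
                self.steps.append(("dropout", entry["rate"]))
            else:
                raise ValueError(f"dnn cannot use layer {entry['type']!r}")
        self.out = Dense(d, spec.output_dim, rng)

    def forward(self, x, training=False, rng=None):
        h = Tensor(np.atleast_2d(np.asarray(x, dtype=DTYPE)))
        for kind, obj in self.steps:
            if kind == "dense":
                h = obj(h)
            else:
                h = ag.dropout(h, obj, rng, training)
        return self.out(h)

    def parameters(self):
        ps = [p for k, l in self.steps if k == "dense" for p in l.parameters()]
        return ps + self.out.parameters()


class _CNNNet:
    """1-D or 2-D convolutional net; summary mode averages block features."""

    def __init__(self, spec, input_shape, rng):
        act = _act(spec.activation)
        two_d = spec.family == "cnn2d"
        self.two_d = two_d
        self.summary = spec.input_mode == "summary"
        self.convs, self.denses = [], []
        channels = 1
        length = (input_shape, input_shape) if two_d else (int(input_shape),)
        for entry in spec.layer_plan:
            if entry["type"] == "conv":
                k = entry["kernel"]
                cls = Conv2D if two_d else Conv1D
                self.convs.append(("conv", cls(channels, entry["filters"], k, rng, act)))
                channels = entry["filters"]
                length = tuple(l - k + 1 for l in length)
            elif entry["type"] == "pool":
                self.convs.append(("pool", entry["size"]))
                length = tuple(l // entry["size"] for l in length)
            elif entry["type"] == "dense":
                self.denses.append(entry["units"])
            elif entry["type"] == "dropout":
                self.denses.append(("dropout", entry["rate"]))
            else:
                raise ValueError(f"cnn cannot use layer {entry['type']!r}")
        if any(l <= 0 for l in length):
            raise ValueError("kernel/pooling plan exhausts the input length")
        flat = channels * int(np.prod(length))
        self.head = []
        d = flat
        for units in self.denses:
            if isinstance(units, tuple):
                self.head.append(("dropout", units[1]))
                continue
            self.head.append(("dense", Dense(d, units, rng, act)))
            d = units
        self.out = Dense(d, spec.output_dim, rng)

    def forward(self, x, training=False, rng=None):
        x = np.asarray(x, dtype=DTYPE)
        if self.summary:
            # blocks arrive as (n_blocks, b, b); blocks act as the batch
            h = Tensor(x[..., None] if self.two_d else
                       x.reshape(x.shape[0], -1, 1))
        else:
            h = Tensor(np.atleast_2d(x)[:, :, None])
        for kind, obj in self.convs:
            if kind == "conv":
                h = obj(h)
            else:
                h = (ag.maxpool2d if self.two_d else ag.maxpool1d)(h, obj)
        h = h.reshape(h.shape[0], -1)
        if self.summary:
            h = h.mean(axis=0, keepdims=True)  # average block representations
        for kind, obj in self.head:
            h = obj(h) if kind == "dense" else ag.dropout(h, obj, rng, training)
        return self.out(h)

    def parameters(self):
        ps = [p for k, l in self.convs if k == "conv" for p in l.parameters()]
        ps += [p for k, l in self.head if k == "dense" for p in l.parameters()]
        return ps + self.out.parameters()


class _LSTMNet:
    """Stacked (Bi)LSTM over the SNP sequence; last step feeds a dense output.

    Individual mode treats the p SNPs as p timesteps of one feature;
    summary mode feeds the p×p LD matrix as p timesteps of p features.
    """

    def __init__(self, spec, input_shape, rng):
        self.summary = spec.input_mode == "summary"
        n_feat = int(input_shape) if self.summary else 1
        self.layers = []
        d = n_feat
        for entry in spec.layer_plan:
            if entry["type"] == "lstm":
                self.layers.append(LSTMLayer(d, entry["units"], rng))
                d = entry["units"]
            elif entry["type"] == "bilstm":
                self.layers.append(BiLSTMLayer(d, entry["units"], rng))
                d = 2 * entry["units"]
            else:
                raise ValueError(f"lstm cannot use layer {entry['type']!r}")
        self.out = Dense(d, spec.output_dim, rng)

    def forward(self, x, training=False, rng=None):
        x = np.asarray(x, dtype=DTYPE)
        if self.summary:
            x = x[None, :, :] if x.ndim == 2 else x
        else:
            x = np.atleast_2d(x)[:, :, None]
        xs = [Tensor(np.ascontiguousarray(x[:, t, :])) for t in range(x.shape[1])]
        for layer in self.layers:
            xs = layer(xs)
        return self.out(xs[-1])

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()] + \
            self.out.parameters()


class _EncoderBlock:
    """Self-attention + dropout + residual layer norm."""

    def __init__(self, d_model, n_heads, drop, rng):
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.norm = LayerNorm(d_model)
        self.drop = drop

    def __call__(self, h, training, rng):
        a = ag.dropout(self.attn(h), self.drop, rng, training)
        return self.norm(h + a)

    def parameters(self):
        return self.attn.parameters() + self.norm.parameters()


class _TransformerIndividualNet:
    """Per-window encoder over SNP tokens, window outputs averaged.

    Each sliding window of SNPs becomes a token sequence (one scalar per
    SNP, linearly embedded); attention outputs are mean-pooled over tokens
    and averaged across windows before the final feedforward layer.
    """

    def __init__(self, spec, input_shape, rng):
        o = spec.options
        p = int(input_shape)
        self.windows = window_slices(p, min(o.get("window", 1000), p),
                                     o.get("stride", 500),
                                     strict=o.get("strict", False))
        d = o.get("d_model", 48)
        self.embed = Dense(1, d, rng)
        self.pe = positional_encoding(self.windows.intervals[0][1]
                                      - self.windows.intervals[0][0], d)
        self.block = _EncoderBlock(d, o.get("n_heads", 6), o.get("dropout", 0.1), rng)
        self.ff = Dense(d, o.get("ff_units", 64), rng, _act(spec.activation))
        self.out = Dense(o.get("ff_units", 64), spec.output_dim, rng)

    def forward(self, x, training=False, rng=None):
        x = np.atleast_2d(np.asarray(x, dtype=DTYPE))
        pooled = []
        for start, stop in self.windows:
            tok = Tensor(x[:, start:stop, None])
            h = self.embed(tok) + Tensor(self.pe)
            h = self.block(h, training, rng)
            pooled.append(h.mean(axis=1))
        avg = pooled[0] if len(pooled) == 1 else \
            ag.stack(pooled, axis=0).mean(axis=0)
        return self.out(self.ff(avg))

    def parameters(self):
        return (self.embed.parameters() + self.block.parameters()
                + self.ff.parameters() + self.out.parameters())


class _TransformerSummaryNet:
    """Encoder over LD-block rows; block representations averaged.

    Rows of each diagonal block are tokens (b tokens of b features),
    embedded to d_model with positional encoding, passed through encoder
    blocks of {multi-head attention, dropout, layer norm}, mean-pooled
    over tokens and averaged across blocks; a two-layer dense head with
    dropout and layer norm precedes the linear n_tr-unit output.
    """

    def __init__(self, spec, input_shape, rng):
        o = spec.options
        b = int(input_shape)
        d = o.get("d_model", 128)
        drop = o.get("dropout", 0.1)
        self.embed = Dense(b, d, rng)
        self.pe = positional_encoding(b, d)
        self.blocks = [_EncoderBlock(d, o.get("n_heads", 6), drop, rng)
                       for _ in range(o.get("n_encoder_blocks", 2))]
        act = _act(spec.activation)
        ff = o.get("ff_units", 128)
        self.ff1 = Dense(d, ff, rng, act)
        self.ff2 = Dense(ff, ff, rng, act)
        self.drop = drop
        self.norm = LayerNorm(ff)
        self.out = Dense(ff, spec.output_dim, rng)

    def forward(self, x, training=False, rng=None):
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 2:
            x = x[None]
        h = self.embed(Tensor(x)) + Tensor(self.pe)
        for blk in self.blocks:
            h = blk(h, training, rng)
        h = h.mean(axis=1)            # pool tokens within each block
        h = h.mean(axis=0, keepdims=True)  # average across blocks
        h = self.ff2(self.ff1(h))
        h = ag.dropout(h, self.drop, rng, training)
        return self.out(self.norm(h))

    def parameters(self):
        ps = self.embed.parameters()
        for blk in self.blocks:
            ps += blk.parameters()
        return (ps + self.ff1.parameters() + self.ff2.parameters()
                + self.norm.parameters() + self.out.parameters())


# ---------------------------------------------------------------------


class PredictorModel:
    """A built network plus its spec; forward output length is output_dim."""

    def __init__(self, spec: ArchitectureSpec, net, input_shape, seed: int):
        self.spec = spec
        self.net = net
        self.input_shape = input_shape
        self.seed = seed

    def forward(self, x, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        if training:
            return self.net.forward(x, training=True, rng=rng)
        with ag.no_grad():
            return self.net.forward(x, training=False, rng=rng)

    def predict(self, x) -> np.ndarray:
        out = self.forward(self.pack_input(x)).data.astype(np.float64)
        if self.spec.input_mode == "summary":
            return out.reshape(-1)
        return out[:, 0] if self.spec.output_dim == 1 else out

    def pack_input(self, x):
        """Accept LDMatrix / LDBlockSet / arrays and emit the net's layout."""
        if isinstance(x, LDBlockSet):
            return x.as_array()
        if isinstance(x, LDMatrix):
            if self.spec.input_mode == "summary" and self.spec.family == "dnn":
                from .ld import upper_triangle
                return upper_triangle(x, self.spec.options.get("include_diagonal", True))
            return x.values
        return np.asarray(x)

    def parameters(self):
        return self.net.parameters()

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


_NETS = {
    "dnn": _DNNNet,
    "cnn1d": _CNNNet,
    "cnn2d": _CNNNet,
    "lstm": _LSTMNet,
    "bilstm": _LSTMNet,
}


def build_model(spec: ArchitectureSpec, input_shape, seed: int = 0) -> PredictorModel:
    """Instantiate a spec with deterministic (seeded) initial weights.

    ``input_shape`` is the per-family input size: the feature-vector
    length for DNN, the sequence length (p) for 1-D CNN and LSTM modes,
    and the block/matrix side length for 2-D and summary block inputs.
    """
    rng = np.random.default_rng(seed)
    if spec.family == "transformer":
        cls = (_TransformerSummaryNet if spec.input_mode == "summary"
               else _TransformerIndividualNet)
    else:
        cls = _NETS[spec.family]
    return PredictorModel(spec, cls(spec, input_shape, rng), input_shape, seed)


def predict(model: PredictorModel, x) -> np.ndarray:
    """Evaluation-mode forward pass (dropout disabled)."""
    return model.predict(x)


# ---------------------------------------------------------------------
# named presets reproducing the benchmark architectures


def _dense(units):
    return {"type": "dense", "units": units}


def _conv(filters, kernel):
    return {"type": "conv", "filters": filters, "kernel": kernel}


_DNN_PLAN = (_dense(231), {"type": "dropout", "rate": 0.2}, _dense(77),
             _dense(22), {"type": "dropout", "rate": 0.5}, _dense(5))

PRESETS: dict[str, dict[str, Any]] = {
    "dnn-paper": dict(family="dnn", layer_plan=_DNN_PLAN),
    "cnn-sim-s1": dict(family="cnn1d", layer_plan=(_conv(50, 500), _dense(50))),
    "cnn-sim-s2": dict(family="cnn1d",
                       layer_plan=(_conv(50, 500),) + (_dense(50),) * 5),
    "cnn-sim-s1-2d": dict(family="cnn2d", layer_plan=(_conv(50, 50), _dense(50))),
    "cnn-sim-s2-2d": dict(family="cnn2d",
                          layer_plan=(_conv(50, 50),) + (_dense(50),) * 5),
    "cnn-real-s1": dict(family="cnn1d",
                        layer_plan=(_conv(32, 5), {"type": "pool", "size": 2},
                                    _dense(50))),
    "cnn-real-s2": dict(family="cnn1d",
                        layer_plan=(_conv(32, 5), {"type": "pool", "size": 2})
                        + ((_conv(64, 3), {"type": "pool", "size": 2}) * 3)
                        + (_dense(50),) * 5),
    "cnn-real-s1-2d": dict(family="cnn2d",
                           layer_plan=(_conv(32, 5), {"type": "pool", "size": 2},
                                       _dense(50))),
    "cnn-real-s2-2d": dict(family="cnn2d",
                           layer_plan=(_conv(32, 5), {"type": "pool", "size": 2})
                           + ((_conv(64, 3), {"type": "pool", "size": 2}) * 3)
                           + (_dense(50),) * 5),
    "lstm-paper": dict(family="lstm", layer_plan=({"type": "lstm", "units": 10},) * 5),
    "bilstm-paper": dict(family="bilstm",
                         layer_plan=({"type": "bilstm", "units": 10},) * 2),
    "transformer-individual": dict(
        family="transformer",
        layer_plan=({"type": "encoder"},),
        options={"window": 1000, "stride": 500, "d_model": 48, "n_heads": 6,
                 "ff_units": 64, "dropout": 0.1}),
    "transformer-summary": dict(
        family="transformer",
        layer_plan=({"type": "encoder"},) * 2,
        options={"d_model": 128, "n_heads": 6, "n_encoder_blocks": 2,
                 "ff_units": 128, "dropout": 0.1}),
}


def architecture(name: str, input_mode: str = "individual",
                 output_dim: int = 1, **overrides) -> ArchitectureSpec:
    """Look up a named preset as an :class:`ArchitectureSpec`.

    ``overrides`` may replace any spec field (e.g. a smaller
    ``layer_plan`` for quick runs) or extend ``options``.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
    base = dict(PRESETS[name])
    options = dict(base.pop("options", {}))
    options.update(overrides.pop("options", {}))
    base.update(overrides)
    return ArchitectureSpec(input_mode=input_mode, output_dim=output_dim,
                            options=options, **base)
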