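"""Fitting predictor models on individual-level or LD-summary inputs.

Both modes minimise the mean-squared loss L(O, Y) = (1/n) Σ (O_i − Y_i)²
with Adam under a per-epoch exponential learning-rate decay. Individual
mode runs shuffled minibatch passes over the sample rows. Summary mode
has exactly one training example — the LD input paired with the whole
training phenotype vector — so each epoch is one full-gradient step and
the configured batch size is recorded but inert.
"""

from __future__ import annotations

import contextlib
import gc
from dataclasses import dataclass, replace

import numpy as np

from ._nn.optim import Adam
from .ld import LDBlockSet, LDMatrix, partition_blocks, upper_triangle
from .models import PredictorModel

__all__ = ["TrainConfig", "FitResult", "TRAIN_PRESETS", "train_config",
           "mse_loss", "lr_at_epoch", "fit_individual", "fit_summary"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 256
    initial_lr: float = 1e-3
    decay_rate: float = 0.96
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 < self.decay_rate <= 1.0):
            raise ValueError("decay_rate must lie in (0, 1]")
        if self.initial_lr <= 0.0:
            raise ValueError("initial_lr must be positive")


TRAIN_PRESETS = {
    "dnn-paper": TrainConfig(epochs=100, batch_size=256, initial_lr=1e-3,
                             decay_rate=0.96),
    "cnn-paper": TrainConfig(epochs=200, batch_size=32, initial_lr=0.1,
                             decay_rate=0.98),
    "lstm-paper": TrainConfig(epochs=10, batch_size=256, initial_lr=1e-3,
                              decay_rate=0.96),
    "bilstm-paper": TrainConfig(epochs=5, batch_size=256, initial_lr=1e-3,
                                decay_rate=0.96),
    "transformer-paper": TrainConfig(epochs=10, batch_size=8, initial_lr=1e-3,
                                     decay_rate=0.96),
}


def train_config(name: str, **overrides) -> TrainConfig:
    if name not in TRAIN_PRESETS:
        raise KeyError(f"unknown train preset {name!r}; known: {sorted(TRAIN_PRESETS)}")
    return replace(TRAIN_PRESETS[name], **overrides)


@dataclass
class FitResult:
    model: PredictorModel
    loss_history: list[float]
    final_train_error: float


def mse_loss(outputs, targets) -> float:
    """Mean squared difference (1/n) Σ (O_i − Y_i)²."""
    outputs = np.asarray(outputs, dtype=np.float64).reshape(-1)
    targets = np.asarray(targets, dtype=np.float64).reshape(-1)
    if outputs.shape != targets.shape:
        raise ValueError(f"length mismatch: {outputs.shape} vs {targets.shape}")
    d = outputs - targets
    return float(d @ d / d.size)


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Exponential schedule: initial_lr · decay_rate**epoch."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.initial_lr * config.decay_rate ** epoch


def _loss_tensor(out, target: np.ndarray):
    diff = out.reshape(-1) - target
    return (diff * diff).mean()


@contextlib.contextmanager
def _gc_paused():
    """Pause cyclic GC while a graph is live; it is acyclic, refcounts free it."""
    was_enabled = gc.isenabled()
    gc.disable()
    try:
        yield
    finally:
        if was_enabled:
            gc.enable()


def _check_finite(value: float, epoch: int) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(
            f"training loss became non-finite at epoch {epoch}; "
            "lower the learning rate or rescale inputs")


def fit_individual(model: PredictorModel, X: np.ndarray, y: np.ndarray,
                   config: TrainConfig) -> FitResult:
    """Shuffled minibatch training of a one-output model on sample rows."""
    if model.spec.output_dim != 1:
        raise ValueError("individual mode requires output_dim == 1")
    X = np.asarray(X)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    if X.shape[0] != y.size:
        raise ValueError("row count must match phenotype length")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.initial_lr)
    history = []
    n = y.size
    with _gc_paused():
        for epoch in range(config.epochs):
            opt.lr = lr_at_epoch(config, epoch)
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                out = model.forward(X[idx], training=True, rng=rng)
                loss = _loss_tensor(out, y[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                loss_val = float(loss.data)
                out = loss = None  # free the graph before the next batch
                epoch_loss += loss_val * idx.size
                seen += idx.size
            mean_loss = epoch_loss / seen
            _check_finite(mean_loss, epoch)
            history.append(mean_loss)
    final = mse_loss(model.predict(X), y)
    return FitResult(model, history, final)


def summary_input(model: PredictorModel, ld) -> np.ndarray:
    """Convert an LDMatrix/LDBlockSet into the family's summary layout."""
    spec = model.spec
    if isinstance(ld, LDBlockSet):
        if spec.family in ("lstm", "bilstm", "dnn"):
            raise ValueError(f"{spec.family} summary mode takes the full LD matrix")
        return ld.as_array()
    if isinstance(ld, LDMatrix):
        if spec.family == "dnn":
            return upper_triangle(ld, spec.options.get("include_diagonal", True))
        if spec.family in ("lstm", "bilstm"):
            return ld.values
        block_size = spec.options.get("block_size")
        if block_size:
            return partition_blocks(ld, block_size).as_array()
        return ld.values[None, :, :]  # single block
    return np.asarray(ld)


def fit_summary(model: PredictorModel, ld_train, y_train: np.ndarray,
                config: TrainConfig) -> FitResult:
    """Train on the single (LD input, training phenotypes) example.

    Each epoch performs one gradient step; the loss is the mean squared
    difference between the n_tr outputs and the n_tr training phenotypes.
    """
    y = np.asarray(y_train, dtype=np.float64).reshape(-1)
    if model.spec.output_dim != y.size:
        raise ValueError(
            f"summary mode requires output_dim == n_tr ({y.size}), "
            f"got {model.spec.output_dim}")
    x = summary_input(model, ld_train)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.initial_lr)
    history = []
    with _gc_paused():
        for epoch in range(config.epochs):
            opt.lr = lr_at_epoch(config, epoch)
            out = model.forward(x, training=True, rng=rng)
            loss = _loss_tensor(out, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            loss_val = float(loss.data)
            out = loss = None
            _check_finite(loss_val, epoch)
            history.append(loss_val)
    final = mse_loss(model.forward(x).data.reshape(-1), y)
    return FitResult(model, history, final)
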