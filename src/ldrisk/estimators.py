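"""scikit-learn style estimators wrapping the model zoo and BLUP.

These classes are the user-facing fitting surface: they follow the
``fit``/``predict``/``get_params`` contract, validate inputs, and expose
fitted state through trailing-underscore attributes, so they compose with
sklearn pipelines, ``clone`` and cross-validation. The module-level
functions in :mod:`ldrisk.training` and :mod:`ldrisk.blup` remain the
thin functional layer beneath them.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import blup as blup_mod
from .ld import LDBlockSet, LDMatrix
from .models import ArchitectureSpec, architecture, build_model
from .training import (TrainConfig, fit_individual, fit_summary, mse_loss,
                       summary_input, train_config)

__all__ = ["DeepGenomicRegressor", "BLUPRegressor"]

# architecture preset -> default training-schedule preset
_DEFAULT_TRAIN = {
    "dnn": "dnn-paper",
    "cnn1d": "cnn-paper",
    "cnn2d": "cnn-paper",
    "lstm": "lstm-paper",
    "bilstm": "bilstm-paper",
    "transformer": "transformer-paper",
}


class DeepGenomicRegressor(BaseEstimator, RegressorMixin):
    """Deep model for trait prediction from genotypes or LD summaries.

    Parameters
    ----------
    architecture : str
        Name of a model-zoo preset (e.g. ``"dnn-paper"``, ``"lstm-paper"``,
        ``"cnn-sim-s1"``, ``"transformer-summary"``).
    mode : {"individual", "summary"}
        ``"individual"`` fits rows of standardized dosages to per-sample
        trait values; ``"summary"`` fits a single LD input to the whole
        training phenotype vector, with one output unit per training
        sample.
    train_preset : str or None
        Training-schedule preset; defaults to the family's benchmark
        schedule (epochs, batch size, learning rate, decay).
    epochs, batch_size, learning_rate, decay_rate : optional overrides
        of the preset schedule.
    block_size : int or None
        In summary mode, cut the LD matrix into diagonal blocks of this
        size before feeding CNN/transformer families.
    arch_overrides : dict or None
        Keyword overrides forwarded to the architecture preset (e.g. a
        smaller ``layer_plan`` or transformer ``options``).
    random_state : int
        Seeds weight initialisation, batch shuffling and dropout.

    Attributes
    ----------
    model_ : PredictorModel
        The trained network.
    loss_history_ : list of float
        Per-epoch training loss.
    final_train_error_ : float
        Training MSE after the last epoch.
    """

    def __init__(self, architecture: str = "dnn-paper",
                 mode: str = "individual", train_preset: str | None = None,
                 epochs: int | None = None, batch_size: int | None = None,
                 learning_rate: float | None = None,
                 decay_rate: float | None = None, block_size: int | None = None,
                 arch_overrides: dict | None = None, random_state: int = 0):
        self.architecture = architecture
        self.mode = mode
        self.train_preset = train_preset
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.decay_rate = decay_rate
        self.block_size = block_size
        self.arch_overrides = arch_overrides
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _train_config(self, family: str) -> TrainConfig:
        name = self.train_preset or _DEFAULT_TRAIN[family]
        overrides = {k: v for k, v in {
            "epochs": self.epochs, "batch_size": self.batch_size,
            "initial_lr": self.learning_rate, "decay_rate": self.decay_rate,
        }.items() if v is not None}
        overrides["seed"] = self.random_state
        return train_config(name, **overrides)

    def _spec(self, output_dim: int) -> ArchitectureSpec:
        overrides = dict(self.arch_overrides or {})
        if self.mode == "summary" and self.block_size:
            options = dict(overrides.get("options", {}))
            options["block_size"] = self.block_size
            overrides["options"] = options
        return architecture(self.architecture, input_mode=self.mode,
                            output_dim=output_dim, **overrides)

    def _input_shape(self, spec: ArchitectureSpec, X) -> int:
        if self.mode == "individual":
            return X.shape[1]
        if isinstance(X, LDBlockSet):
            return X.block_size
        p = X.p if isinstance(X, LDMatrix) else np.asarray(X).shape[-1]
        if spec.family == "dnn":
            k = 0 if spec.options.get("include_diagonal", True) else 1
            return p * (p + 1) // 2 if k == 0 else p * (p - 1) // 2
        if spec.family in ("lstm", "bilstm"):
            return p
        return self.block_size or p

    # ------------------------------------------------------------------
    def fit(self, X, y):
        """Fit to (samples × SNPs, trait) or (LD input, training traits)."""
        if self.mode not in ("individual", "summary"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "individual":
            X, y = check_X_y(X, y, y_numeric=True)
            spec = self._spec(output_dim=1)
            config = self._train_config(spec.family)
            model = build_model(spec, self._input_shape(spec, X),
                                seed=self.random_state)
            result = fit_individual(model, X, y, config)
            self.n_features_in_ = X.shape[1]
        else:
            y = np.asarray(y, dtype=np.float64).reshape(-1)
            spec = self._spec(output_dim=y.size)
            config = self._train_config(spec.family)
            model = build_model(spec, self._input_shape(spec, X),
                                seed=self.random_state)
            result = fit_summary(model, X, y, config)
        self.model_ = result.model
        self.loss_history_ = result.loss_history
        self.final_train_error_ = result.final_train_error
        return self

    def predict(self, X):
        """Per-sample predictions (individual) or the n_tr outputs (summary)."""
        check_is_fitted(self, "model_")
        if self.mode == "individual":
            X = check_array(X)
            if X.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"X has {X.shape[1]} SNPs, expected {self.n_features_in_}")
            return self.model_.predict(X)
        return self.model_.forward(
            summary_input(self.model_, X)).data.astype(np.float64).reshape(-1)

    def score(self, X, y):
        """Negative MSE (higher is better, sklearn convention)."""
        return -mse_loss(self.predict(X), y)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.non_deterministic = False
        return tags


class BLUPRegressor(BaseEstimator, RegressorMixin):
    """Ridge-equivalent best linear unbiased predictor.

    Variance components are REML-estimated on fit unless both
    ``sigma_u2`` and ``sigma_e2`` are supplied. ``predict`` returns
    ``intercept_ + X @ coef_``; the intercept is the training mean.
    """

    def __init__(self, sigma_u2: float | None = None,
                 sigma_e2: float | None = None):
        self.sigma_u2 = sigma_u2
        self.sigma_e2 = sigma_e2

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if self.sigma_u2 is not None and self.sigma_e2 is not None:
            vc = blup_mod.VarianceComponents(self.sigma_u2, self.sigma_e2)
        else:
            vc = blup_mod.estimate_variance_components(X, y)
        self.vc_ = vc
        self.sigma_u2_, self.sigma_e2_ = vc.sigma_u2, vc.sigma_e2
        self.intercept_ = float(y.mean())
        if vc.sigma_u2 == 0.0:
            self.coef_ = np.zeros(X.shape[1])
        else:
            K = X @ X.T
            self.coef_ = X.T @ np.linalg.solve(
                K + vc.ridge_penalty * np.eye(X.shape[0]), y - self.intercept_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self.intercept_ + X @ self.coef_
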