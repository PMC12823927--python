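"""Test-error evaluation, including the bootstrap estimator for summary mode.

A summary-trained model emits n_tr outputs from the *test* LD matrix but
there are only n_te test phenotypes, so the test MSE is approximated by
resampling: draw n_te outputs with replacement, pair them positionally
with the test responses, record the MSE, and average over B draws,

    TE-hat = (1/B) Σ_b TE_b .

Because the draws are uniform and exchangeable, the exact B→∞ limit of
TE-hat is the all-pairs mean (1/(n_tr·n_te)) Σ_j Σ_i (O_j − y_i)², which
equals Var(O) + Var(y) + (mean O − mean y)²; that closed form serves as
the independent oracle for the resampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import simulate as sim
from .training import mse_loss

__all__ = ["OutputVector", "BootstrapEstimate", "test_error_individual",
           "bootstrap_test_error", "allpairs_oracle", "replicate_experiment"]


@dataclass
class OutputVector:
    """The n_tr model outputs produced from one LD input."""

    values: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)
        if not np.isfinite(self.values).all():
            raise ValueError("outputs contain non-finite entries")


@dataclass
class BootstrapEstimate:
    te_hat: float
    resample_errors: np.ndarray
    seed: int
    B: int = field(init=False)
    mc_se: float = field(init=False)

    def __post_init__(self):
        self.resample_errors = np.asarray(self.resample_errors, dtype=np.float64)
        self.B = self.resample_errors.size
        self.mc_se = float(self.resample_errors.std(ddof=1) / np.sqrt(self.B)) \
            if self.B > 1 else 0.0


def test_error_individual(model, X_test, y_test) -> float:
    """MSE of a one-output model's predictions on held-out rows."""
    if model.spec.output_dim != 1:
        raise ValueError("individual-mode evaluation requires output_dim == 1")
    return mse_loss(model.predict(np.asarray(X_test)), y_test)


def bootstrap_test_error(outputs, y_test, B: int = 1000,
                         seed: int = 0) -> BootstrapEstimate:
    """Resampled test-error estimate TE-hat from n_tr outputs.

    For each of the B rounds, n_te outputs are drawn uniformly with
    replacement and the i-th draw is paired with the i-th test response.
    """
    o = outputs.values if isinstance(outputs, OutputVector) else \
        np.asarray(outputs, dtype=np.float64).reshape(-1)
    y = np.asarray(y_test, dtype=np.float64).reshape(-1)
    if o.size == 0 or y.size == 0:
        raise ValueError("outputs and y_test must be non-empty")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, o.size, size=(B, y.size))
    errors = ((o[idx] - y) ** 2).mean(axis=1)
    return BootstrapEstimate(float(errors.mean()), errors, seed)


def allpairs_oracle(outputs, y_test) -> float:
    """Exact B→∞ limit: the mean of (O_j − y_i)² over all pairs (j, i)."""
    o = outputs.values if isinstance(outputs, OutputVector) else \
        np.asarray(outputs, dtype=np.float64).reshape(-1)
    y = np.asarray(y_test, dtype=np.float64).reshape(-1)
    if o.size == 0 or y.size == 0:
        raise ValueError("outputs and y_test must be non-empty")
    return float(o.var() + y.var() + (o.mean() - y.mean()) ** 2)


def replicate_experiment(sim_config, method_specs, R: int = 20, B: int = 1000,
                         seed: int = 0, redraw_phenotypes: bool = False,
                         maf_threshold: float = 0.001) -> pd.DataFrame:
    """Repeat the simulation benchmark R times and tabulate mean (sd) errors.

    ``method_specs`` is a list of dicts, each naming a method row:
    ``{"name", "architecture", "train", "modes", ...}`` where
    ``architecture``/``train`` are preset names (or explicit spec/config
    objects), ``modes`` a subset of {"individual", "summary"} and optional
    keys ``arch_overrides``/``train_overrides``/``block_size`` adjust the
    presets. Each repetition draws a fresh train/test split (and, when
    ``redraw_phenotypes``, a fresh phenotype), fits every method in every
    requested mode and records the training error, the individual-level
    test MSE and the bootstrap summary test error. The returned frame has
    one row per (method, mode) with per-cell mean and sd over the R runs,
    mirroring a method-by-mode error table.
    """
    from . import ld as ldmod
    from .models import ArchitectureSpec, architecture, build_model
    from .training import (TrainConfig, fit_individual, fit_summary,
                           summary_input, train_config)

    if R < 1:
        raise ValueError("R must be >= 1")
    G = sim.filter_maf(sim.simulate_genotypes(sim_config), maf_threshold)
    Gstd = sim.standardize(G)
    base_pheno = sim.simulate_phenotype(Gstd, sim_config)
    p = Gstd.n_snps
    records = []
    for r in range(R):
        split = sim.split_data(Gstd.n_samples, sim_config.train_fraction,
                               seed + 1000 + r)
        pheno = sim.simulate_phenotype(Gstd, sim_config, seed=seed + 2000 + r) \
            if redraw_phenotypes else base_pheno
        y_tr = pheno.values[split.train_indices]
        y_te = pheno.values[split.test_indices]
        ld_tr = ldmod.compute_ld(Gstd, split.train_indices)
        ld_te = ldmod.compute_ld(Gstd, split.test_indices)
        for m in method_specs:
            name = m["name"]
            tc = m["train"] if isinstance(m["train"], TrainConfig) else \
                train_config(m["train"], **m.get("train_overrides", {}))
            tc = tc.__class__(**{**tc.__dict__, "seed": seed + 3000 + r})
            for mode in m.get("modes", ("individual", "summary")):
                try:
                    rec = _run_one(m, name, mode, Gstd, split, y_tr, y_te,
                                   ld_tr, ld_te, tc, B, seed + 4000 + r, p)
                except Exception as exc:
                    raise RuntimeError(
                        f"method {name!r} mode {mode!r} failed in run {r}") from exc
                rec.update(run=r)
                records.append(rec)
    df = pd.DataFrame(records)
    out = df.groupby(["method", "mode"], sort=False).agg(
        train_error_mean=("train_error", "mean"),
        train_error_sd=("train_error", "std"),
        test_error_mean=("test_error", "mean"),
        test_error_sd=("test_error", "std"),
    ).reset_index()
    return out


def _run_one(m, name, mode, Gstd, split, y_tr, y_te, ld_tr, ld_te, tc, B,
             eval_seed, p):
    from . import ld as ldmod
    from .models import ArchitectureSpec, architecture, build_model
    from .training import fit_individual, fit_summary, summary_input

    arch = m["architecture"]
    overrides = dict(m.get("arch_overrides", {}))
    block_size = m.get("block_size")
    if mode == "summary":
        output_dim = y_tr.size
        if block_size:
            overrides.setdefault("options", {})
            overrides["options"] = {**overrides["options"], "block_size": block_size}
    else:
        output_dim = 1
    spec = arch if isinstance(arch, ArchitectureSpec) else \
        architecture(arch, input_mode=mode, output_dim=output_dim, **overrides)
    if mode == "individual":
        shape = p
    elif spec.family == "dnn":
        shape = None  # set below from the upper-triangle length
    elif spec.family in ("lstm", "bilstm"):
        shape = p
    else:
        shape = block_size if block_size else p
    if mode == "individual":
        model = build_model(spec, shape, seed=tc.seed)
        fit = fit_individual(model, Gstd.values[split.train_indices], y_tr, tc)
        test_err = test_error_individual(model, Gstd.values[split.test_indices], y_te)
    else:
        if spec.family == "dnn":
            shape = p * (p + 1) // 2 if spec.options.get("include_diagonal", True) \
                else p * (p - 1) // 2
        model = build_model(spec, shape, seed=tc.seed)
        fit = fit_summary(model, ld_tr, y_tr, tc)
        outputs = OutputVector(model.forward(summary_input(model, ld_te)).data,
                               source=name)
        test_err = bootstrap_test_error(outputs, y_te, B=B, seed=eval_seed).te_hat
    return dict(method=name, mode=mode, train_error=fit.final_train_error,
                test_error=test_err)
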