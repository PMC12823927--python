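"""Loss, learning-rate schedule, and both fitting modes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldrisk import ld as ldmod
from ldrisk.models import ArchitectureSpec, build_model
from ldrisk.training import (TRAIN_PRESETS, TrainConfig, fit_individual,
                             fit_summary, lr_at_epoch, mse_loss, train_config)

vec = st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=30)


class TestMseLoss:
    def test_identity_gives_zero(self, rng):
        y = rng.standard_normal(10)
        assert mse_loss(y, y) == 0.0

    def test_hand_computed(self):
        assert mse_loss([1.0, 2.0], [0.0, 0.0]) == pytest.approx(2.5)

    @given(o=vec, c=st.floats(-100, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_translation_invariance(self, o, c):
        o = np.asarray(o)
        y = np.zeros_like(o)
        assert mse_loss(o + c, y + c) == pytest.approx(mse_loss(o, y), rel=1e-6,
                                                       abs=1e-9)

    @given(o=vec)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_variance_plus_squared_bias_identity(self, o):
        o = np.asarray(o)
        y = np.linspace(-1, 1, o.size)
        d = o - y
        expect = d.var() + d.mean() ** 2
        assert mse_loss(o, y) == pytest.approx(expect, rel=1e-9, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss([1.0], [1.0, 2.0])


class TestLrSchedule:
    def test_epoch_zero_is_initial(self):
        cfg = TrainConfig(initial_lr=0.05)
        assert lr_at_epoch(cfg, 0) == 0.05

    def test_one_step_decay(self):
        cfg = TrainConfig(initial_lr=1e-3, decay_rate=0.96)
        assert lr_at_epoch(cfg, 1) == pytest.approx(0.00096)

    def test_unit_decay_is_constant(self):
        cfg = TrainConfig(initial_lr=0.01, decay_rate=1.0)
        assert lr_at_epoch(cfg, 57) == 0.01

    def test_benchmark_schedule_is_geometric_over_100_epochs(self):
        cfg = TRAIN_PRESETS["dnn-paper"]
        lrs = [lr_at_epoch(cfg, e) for e in range(cfg.epochs)]
        assert len(lrs) == 100
        ratios = np.diff(np.log(lrs))
        np.testing.assert_allclose(np.exp(ratios), 0.96, rtol=1e-12)

    def test_presets_match_published_schedules(self):
        assert train_config("cnn-paper").epochs == 200
        assert train_config("cnn-paper").initial_lr == pytest.approx(0.1)
        assert train_config("lstm-paper").epochs == 10
        assert train_config("bilstm-paper").epochs == 5
        assert train_config("transformer-paper").batch_size == 8


LINEAR = ArchitectureSpec("dnn", layer_plan=({"type": "dense", "units": 8},))


class TestFitIndividual:
    def test_realizable_linear_regression_is_learned(self, rng):
        X = rng.standard_normal((120, 6))
        beta = rng.standard_normal(6)
        y = X @ beta  # noiseless target within model capacity
        model = build_model(LINEAR, 6, seed=0)
        cfg = TrainConfig(epochs=400, batch_size=32, initial_lr=0.02,
                          decay_rate=0.995, seed=0)
        fit = fit_individual(model, X, y, cfg)
        assert fit.final_train_error < 1e-3

    def test_loss_history_trends_down(self, rng):
        X = rng.standard_normal((100, 6))
        y = X @ rng.standard_normal(6) + 0.1 * rng.standard_normal(100)
        fit = fit_individual(build_model(LINEAR, 6, seed=1), X, y,
                             TrainConfig(epochs=30, batch_size=25,
                                         initial_lr=0.01, seed=1))
        assert len(fit.loss_history) == 30
        assert np.mean(fit.loss_history[-5:]) <= np.mean(fit.loss_history[:5])

    def test_same_seed_reproduces_history(self, rng):
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        cfg = TrainConfig(epochs=5, batch_size=16, seed=3)
        a = fit_individual(build_model(LINEAR, 6, seed=2), X, y, cfg)
        b = fit_individual(build_model(LINEAR, 6, seed=2), X, y, cfg)
        assert a.loss_history == b.loss_history

    def test_multi_output_model_rejected(self, rng):
        spec = ArchitectureSpec("dnn", layer_plan=LINEAR.layer_plan,
                                output_dim=3)
        with pytest.raises(ValueError, match="output_dim"):
            fit_individual(build_model(spec, 6, seed=0),
                           rng.standard_normal((10, 6)),
                           rng.standard_normal(10), TrainConfig(epochs=1))


class TestFitSummary:
    def _ld(self, small_cohort):
        _, Gstd, pheno, split = small_cohort
        ld = ldmod.compute_ld(Gstd, split.train_indices)
        return ld, pheno.values[split.train_indices]

    def test_capacity_allows_memorizing_fixed_target(self, small_cohort):
        # one fixed example: a wide net can drive the loss well below Var(y)
        ld, y = self._ld(small_cohort)
        y50 = y[:50]
        spec = ArchitectureSpec("dnn", "summary",
                                ({"type": "dense", "units": 256},),
                                output_dim=50)
        p = ld.p
        model = build_model(spec, p * (p + 1) // 2, seed=0)
        cfg = TrainConfig(epochs=300, initial_lr=0.01, decay_rate=0.999, seed=0)
        fit = fit_summary(model, ld, y50, cfg)
        assert fit.final_train_error < 0.1 * y50.var()

    def test_constant_target_reaches_zero(self, small_cohort):
        ld, y = self._ld(small_cohort)
        target = np.full(y.size, 3.25)
        spec = ArchitectureSpec("dnn", "summary",
                                ({"type": "dense", "units": 4},),
                                output_dim=y.size)
        p = ld.p
        model = build_model(spec, p * (p + 1) // 2, seed=0)
        fit = fit_summary(model, ld, target,
                          TrainConfig(epochs=800, initial_lr=0.05,
                                      decay_rate=1.0, seed=0))
        assert fit.final_train_error < 1e-3

    def test_epochs_equal_gradient_steps(self, small_cohort):
        ld, y = self._ld(small_cohort)
        spec = ArchitectureSpec("dnn", "summary",
                                ({"type": "dense", "units": 4},),
                                output_dim=y.size)
        p = ld.p
        fit = fit_summary(build_model(spec, p * (p + 1) // 2, seed=0), ld, y,
                          TrainConfig(epochs=7, seed=0))
        assert len(fit.loss_history) == 7

    def test_same_seed_reproduces_result(self, small_cohort):
        ld, y = self._ld(small_cohort)
        spec = ArchitectureSpec("dnn", "summary",
                                ({"type": "dense", "units": 4},),
                                output_dim=y.size)
        p = ld.p
        cfg = TrainConfig(epochs=4, seed=5)
        a = fit_summary(build_model(spec, p * (p + 1) // 2, seed=4), ld, y, cfg)
        b = fit_summary(build_model(spec, p * (p + 1) // 2, seed=4), ld, y, cfg)
        assert a.loss_history == b.loss_history
        assert a.final_train_error == b.final_train_error

    def test_output_dim_mismatch_rejected(self, small_cohort):
        ld, y = self._ld(small_cohort)
        spec = ArchitectureSpec("dnn", "summary",
                                ({"type": "dense", "units": 4},),
                                output_dim=y.size + 1)
        p = ld.p
        with pytest.raises(ValueError, match="n_tr"):
            fit_summary(build_model(spec, p * (p + 1) // 2, seed=0), ld, y,
                        TrainConfig(epochs=1))
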