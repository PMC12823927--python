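"""Simulated genotypes/phenotypes: marginals, LD structure, scaling, splits."""

import numpy as np
import pytest

from ldrisk import simulate as sim


class TestSimulateGenotypes:
    def test_marginals_and_independence_without_block_corr(self):
        cfg = sim.SimulationConfig(n_individuals=10_000, n_snps=30,
                                   block_length=5, within_block_corr=0.0,
                                   maf_range=(0.05, 0.45), seed=3)
        G = sim.simulate_genotypes(cfg)
        assert set(np.unique(G.values)) <= {0.0, 1.0, 2.0}
        # each SNP's sample frequency within 3 binomial sd of its target maf
        freq = G.values.mean(axis=0) / 2.0
        sd = np.sqrt(G.mafs * (1 - G.mafs) / (2 * cfg.n_individuals))
        assert (np.abs(freq - G.mafs) < 3 * sd + 1e-12).mean() > 0.9
        # pairwise dosage correlations centred at zero
        corr = np.corrcoef(G.values.T)
        off = corr[~np.eye(30, dtype=bool)]
        assert abs(off.mean()) < 0.01

    def test_block_correlation_exceeds_between_block(self):
        cfg = sim.SimulationConfig(n_individuals=10_000, n_snps=100,
                                   block_length=5, within_block_corr=0.9,
                                   maf_range=(0.1, 0.45), seed=4)
        G = sim.simulate_genotypes(cfg)
        corr = np.abs(np.corrcoef(G.values.T))
        within, between = [], []
        for a in range(100):
            for b in range(a + 1, 100):
                (within if a // 5 == b // 5 else between).append(corr[a, b])
        assert np.mean(within) > 5 * np.mean(between)

    def test_deterministic_under_seed(self):
        cfg = sim.SimulationConfig(n_individuals=50, n_snps=20, seed=9)
        a = sim.simulate_genotypes(cfg)
        b = sim.simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.mafs, b.mafs)

    @pytest.mark.parametrize("bad", [dict(n_individuals=0), dict(n_snps=-1),
                                     dict(maf_range=(0.0, 0.3)),
                                     dict(maf_range=(0.4, 0.2)),
                                     dict(causal_fraction=0.0),
                                     dict(train_fraction=1.0)])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            sim.SimulationConfig(**bad)


class TestFilterMaf:
    def _toy(self):
        # sample MAFs: 0.0005, 0.001, 0.01, 0.4 on 1000 individuals
        n = 1000
        values = np.zeros((n, 4))
        values[0, 0] = 1          # freq 1/2000 = 0.0005
        values[0, 1] = 2          # freq 2/2000 = 0.001
        values[:10, 2] = 2        # freq 20/2000 = 0.01
        values[:400, 3] = 2       # freq 800/2000 = 0.4
        return sim.GenotypeMatrix(values, [f"v{i}" for i in range(4)],
                                  [f"s{i}" for i in range(n)],
                                  np.array([0.0005, 0.001, 0.01, 0.4]))

    def test_hand_counted_threshold(self):
        out = sim.filter_maf(self._toy(), 0.001)
        assert out.snp_ids == ["v1", "v2", "v3"]
        assert out.n_snps == 3

    def test_zero_threshold_is_identity(self):
        G = self._toy()
        out = sim.filter_maf(G, 0.0)
        np.testing.assert_array_equal(out.values, G.values)

    def test_empty_result_errors(self):
        with pytest.raises(ValueError, match="no SNPs"):
            sim.filter_maf(self._toy(), 0.45)


class TestStandardize:
    def test_columns_have_mean_zero_sd_inv_sqrt_p(self, small_cohort):
        _, Gstd, _, _ = small_cohort
        p = Gstd.n_snps
        assert np.abs(Gstd.values.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(Gstd.values.std(axis=0), 1 / np.sqrt(p),
                                   atol=1e-8)

    def test_hand_computed_two_by_two(self):
        G = sim.GenotypeMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]),
                               ["a", "b"], ["s0", "s1"], np.array([0.5, 0.5]))
        out = sim.standardize(G)
        # column mean 1, population sd 1, then /sqrt(2)
        expect = np.array([[-1, 1], [1, -1]]) / np.sqrt(2)
        np.testing.assert_allclose(out.values, expect)

    def test_single_snp_has_unit_sd(self):
        G = sim.GenotypeMatrix(np.array([[0.0], [1.0], [2.0]]), ["a"],
                               ["s0", "s1", "s2"], np.array([0.5]))
        out = sim.standardize(G)
        np.testing.assert_allclose(out.values.std(), 1.0)

    def test_round_trip_recovers_dosages(self, small_cohort):
        _, Gstd, _, _ = small_cohort
        cfg = small_cohort[0]
        G = sim.filter_maf(sim.simulate_genotypes(cfg), 0.001)
        np.testing.assert_allclose(Gstd.unscale(), G.values, atol=1e-10)

    def test_constant_column_names_the_snp(self):
        G = sim.GenotypeMatrix(np.array([[1.0, 0.0], [1.0, 2.0]]),
                               ["const_snp", "ok"], ["s0", "s1"],
                               np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="const_snp"):
            sim.standardize(G)


class TestSimulatePhenotype:
    def test_model_variance_identity_holds_exactly(self, small_cohort):
        cfg, Gstd, pheno, _ = small_cohort
        # Var(Y) = w' Sigma_causal w + noise^2 given the drawn weights
        Zc = Gstd.values[:, pheno.causal_indices]
        model_var = pheno.weights @ np.cov(Zc.T, ddof=0) @ pheno.weights \
            + cfg.noise_sd ** 2
        genetic = Zc @ pheno.weights
        resid = pheno.values - genetic
        # residuals are the drawn noise: mean ~0, variance ~noise_sd^2
        assert abs(resid.var() - cfg.noise_sd ** 2) < 4 * cfg.noise_sd ** 2 \
            * np.sqrt(2 / cfg.n_individuals)
        assert abs(pheno.values.var() - model_var) < 0.3 * model_var

    def test_variance_matches_law_of_total_variance(self):
        # independent SNPs, defaults: Var(Y) ~ 1 + K * 0.36 / p ~ 1.108
        cfg = sim.SimulationConfig(n_individuals=4000, n_snps=500,
                                   within_block_corr=0.0, seed=5)
        total = []
        for s in range(8):
            G = sim.simulate_genotypes(
                sim.SimulationConfig(**{**cfg.__dict__, "seed": 50 + s}))
            Gstd = sim.standardize(G)
            pheno = sim.simulate_phenotype(Gstd, cfg, seed=90 + s)
            total.append(pheno.values.var())
        assert abs(np.mean(total) - 1.108) < 0.05

    def test_zero_weights_leave_noise_only(self, small_cohort):
        _, Gstd, _, _ = small_cohort
        cfg = sim.SimulationConfig(n_individuals=120, n_snps=50,
                                   causal_fraction=1.0, w_sd=0.0, seed=6)
        pheno = sim.simulate_phenotype(Gstd, cfg)
        assert abs(pheno.values.var() - 1.0) < 0.4

    def test_noiseless_single_causal_equals_column(self, small_cohort):
        _, Gstd, _, _ = small_cohort
        cfg = sim.SimulationConfig(n_individuals=120, n_snps=50,
                                   causal_fraction=1 / 50, noise_sd=1e-300,
                                   seed=7)
        pheno = sim.simulate_phenotype(Gstd, cfg)
        assert pheno.causal_indices.size == 1
        col = Gstd.values[:, pheno.causal_indices[0]]
        np.testing.assert_allclose(pheno.values, col * pheno.weights[0],
                                   atol=1e-12)

    def test_deterministic_under_seed(self, small_cohort):
        _, Gstd, _, _ = small_cohort
        cfg = small_cohort[0]
        a = sim.simulate_phenotype(Gstd, cfg, seed=77)
        b = sim.simulate_phenotype(Gstd, cfg, seed=77)
        np.testing.assert_array_equal(a.values, b.values)


class TestSplitData:
    def test_benchmark_cohort_sizes(self):
        split = sim.split_data(1092, 0.8, seed=0)
        assert (split.n_train, split.n_test) == (873, 219)

    def test_even_split(self):
        split = sim.split_data(10, 0.5, seed=1)
        assert (split.n_train, split.n_test) == (5, 5)

    def test_partition_is_disjoint_and_complete(self):
        split = sim.split_data(101, 0.8, seed=2)
        merged = np.sort(np.concatenate([split.train_indices,
                                         split.test_indices]))
        np.testing.assert_array_equal(merged, np.arange(101))

    def test_deterministic_under_seed(self):
        a, b = sim.split_data(50, 0.7, seed=3), sim.split_data(50, 0.7, seed=3)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)

    @pytest.mark.parametrize("n,frac", [(1, 0.5), (2, 0.1), (5, 1.0)])
    def test_degenerate_splits_rejected(self, n, frac):
        with pytest.raises(ValueError):
            sim.split_data(n, frac, seed=0)
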