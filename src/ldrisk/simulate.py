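"""Genotype and phenotype simulation with blockwise linkage disequilibrium.

The generator emulates a 1 Mb common-variant panel: per-SNP minor allele
frequencies drawn uniformly from a range, dosages organised in consecutive
haplotype blocks with a tunable within-block latent correlation, additive
0/1/2 coding, and a quantitative trait built as a sparse linear combination
of standardized dosages plus Gaussian noise,

    Y_i = sum_k w_k g_ik + eps_i,   w_k ~ N(0, w_sd^2),  eps_i ~ N(0, noise_sd^2),

with a fraction of SNPs (default 30%) carrying nonzero weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "StandardizedGenotypes",
    "PhenotypeVector",
    "DataSplit",
    "simulate_genotypes",
    "filter_maf",
    "standardize",
    "simulate_phenotype",
    "split_data",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one simulated cohort.

    Defaults reproduce the simulation design this package benchmarks
    against: n=1,092 individuals, MAF in [0.001, 0.5), 30% causal SNPs
    with N(0, 0.6^2) effects, unit-variance residual noise and an 80/20
    train/test split.
    """

    n_individuals: int = 1092
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.001, 0.5)
    block_length: int = 20
    within_block_corr: float = 0.7
    causal_fraction: float = 0.30
    w_sd: float = 0.6
    noise_sd: float = 1.0
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        # upper bound 0.5 allowed: uniform draws are half-open so MAF < 0.5
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.n_individuals <= 0 or self.n_snps <= 0 or self.block_length <= 0:
            raise ValueError("dimensions must be positive")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ValueError("within_block_corr must lie in [0, 1)")
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValueError("causal_fraction must lie in (0, 1]")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class GenotypeMatrix:
    """Additive dosages: rows are samples, columns SNPs, entries in {0,1,2}."""

    values: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    mafs: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def sample_mafs(self) -> np.ndarray:
        """Observed minor-allele frequency per column (folded to <= 0.5)."""
        freq = self.values.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class StandardizedGenotypes:
    """Column-standardized dosages: mean 0, sd 1/sqrt(p) per column.

    ``column_means``/``column_sds`` are the raw statistics used for the
    transform, so the original dosages can be recovered exactly.
    """

    values: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    column_means: np.ndarray
    column_sds: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def unscale(self) -> np.ndarray:
        p = self.n_snps
        return self.values * (self.column_sds * np.sqrt(p)) + self.column_means


@dataclass
class PhenotypeVector:
    values: np.ndarray
    causal_indices: np.ndarray
    weights: np.ndarray


@dataclass
class DataSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray

    @property
    def n_train(self) -> int:
        return self.train_indices.size

    @property
    def n_test(self) -> int:
        return self.test_indices.size


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a dosage matrix with blockwise LD via a latent-Gaussian model.

    Each of the two allele copies of a SNP is the indicator that a latent
    standard normal falls below the MAF quantile; latents within a block of
    ``block_length`` consecutive SNPs share an equicorrelation
    ``within_block_corr``, blocks are independent. Marginals are therefore
    Binomial(2, maf) while neighbouring dosages are positively correlated.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_individuals, config.n_snps
    r = config.within_block_corr
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    thresholds = norm.ppf(mafs)

    dosage = np.zeros((n, p), dtype=np.int8)
    sr, sc = np.sqrt(r), np.sqrt(1.0 - r)
    for start in range(0, p, config.block_length):
        width = min(config.block_length, p - start)
        for _copy in range(2):
            shared = rng.standard_normal((n, 1))
            latent = sr * shared + sc * rng.standard_normal((n, width))
            dosage[:, start:start + width] += latent < thresholds[start:start + width]
    snp_ids = [f"snp{j}" for j in range(p)]
    sample_ids = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(dosage.astype(np.float64), snp_ids, sample_ids, mafs)


def filter_maf(G: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop SNPs whose sample MAF falls below ``threshold`` (order kept)."""
    if not (0.0 <= threshold < 0.5):
        raise ValueError("threshold must lie in [0, 0.5)")
    keep = G.sample_mafs() >= threshold
    if not keep.any():
        raise ValueError(f"no SNPs with sample MAF >= {threshold}")
    return GenotypeMatrix(
        values=G.values[:, keep],
        snp_ids=[s for s, k in zip(G.snp_ids, keep) if k],
        sample_ids=list(G.sample_ids),
        mafs=G.mafs[keep],
    )


def standardize(G: GenotypeMatrix, ddof: int = 0) -> StandardizedGenotypes:
    """Scale each SNP column to mean 0 and sd 1/sqrt(p).

    Column j maps to (x - m_j) / (s_j * sqrt(p)). The default sd is the
    population-style estimate (``ddof=0``) so that the LD-matrix diagonal
    equals each column's mean square exactly; pass ``ddof=1`` for the
    n-1 convention.
    """
    p = G.n_snps
    means = G.values.mean(axis=0)
    sds = G.values.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sds == 0.0)
    if bad.size:
        raise ValueError(f"constant genotype column(s): {[G.snp_ids[j] for j in bad[:5]]}")
    values = (G.values - means) / (sds * np.sqrt(p))
    return StandardizedGenotypes(values, list(G.snp_ids), list(G.sample_ids),
                                 means, sds)


def _n_causal(config: SimulationConfig, p: int) -> int:
    # round-half-up so e.g. 0.3 * 5 -> 2
    return int(np.floor(config.causal_fraction * p + 0.5))


def simulate_phenotype(Gstd: StandardizedGenotypes,
                       config: SimulationConfig,
                       seed: int | None = None) -> PhenotypeVector:
    """Draw Y = sum_k w_k g_ik + eps over a random causal subset."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n, p = Gstd.values.shape
    K = _n_causal(config, p)
    if K == 0:
        raise ValueError("causal_fraction yields zero causal SNPs")
    causal = np.sort(rng.choice(p, size=K, replace=False))
    w = rng.normal(0.0, config.w_sd, size=K)
    eps = rng.normal(0.0, config.noise_sd, size=n)
    y = Gstd.values[:, causal] @ w + eps
    return PhenotypeVector(y, causal, w)


def split_data(n: int, train_fraction: float, seed: int) -> DataSplit:
    """Uniform random partition with floor(train_fraction * n) training rows."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    if n < 2:
        raise ValueError("need at least two samples to split")
    n_tr = int(np.floor(train_fraction * n))
    if n_tr == 0 or n_tr == n:
        raise ValueError(f"degenerate split: n_tr={n_tr} of n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return DataSplit(np.sort(perm[:n_tr]), np.sort(perm[n_tr:]))


def simulate_dataset(config: SimulationConfig, maf_threshold: float = 0.001):
    """Full pipeline: genotypes -> MAF filter -> standardize -> phenotype -> split.

    Scaling is computed on the full matrix before splitting, matching the
    benchmarked design where the standardized matrix G is formed once and
    training/test rows are extracted from it afterwards.
    """
    G = filter_maf(simulate_genotypes(config), maf_threshold)
    Gstd = standardize(G)
    pheno = simulate_phenotype(Gstd, config)
    split = split_data(Gstd.n_samples, config.train_fraction, config.seed + 2)
    return Gstd, pheno, split
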