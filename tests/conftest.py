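import numpy as np
import pytest

from ldrisk import simulate as sim


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-sample, 50-SNP simulated cohort shared across tests."""
    cfg = sim.SimulationConfig(n_individuals=120, n_snps=50, block_length=10,
                               within_block_corr=0.6, seed=42)
    Gstd, pheno, split = sim.simulate_dataset(cfg)
    return cfg, Gstd, pheno, split


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
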