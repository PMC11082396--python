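import numpy as np
import pytest

from oatmap import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Small but non-trivial experiment used across module tests."""
    return SimConfig(
        n_chrom=2,
        chrom_bp=300_000,
        chrom_cM=100.0,
        n_genes=30,
        n_mutations=80,
        n_f2=120,
        pool_size=10,
        seed=20240401,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
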