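import numpy as np
import pytest

from atacmem.simulate import SimulationConfig, simulate_truth, simulate_counts


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced design that keeps every category populated but runs fast."""
    return SimulationConfig(
        seed=11,
        n_peaks={"mDHS": 60, "nDHS": 60, "iDHS": 60, "dDHS": 60, "constitutive": 120},
        n_dual_gene_pairs=20,
        genome=(("chr1", 1_500_000), ("chr2", 1_500_000)),
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_truth):
    truth, _ = small_truth
    return simulate_counts(truth, small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
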