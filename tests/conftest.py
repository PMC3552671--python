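import numpy as np
import pytest

from bidipol import SimConfig, default_theta, simulate_cohort


@pytest.fixture(scope="session")
def theta():
    return default_theta()


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny seeded cohort shared by the cheaper integration tests."""
    return simulate_cohort(SimConfig(seed=123, n_genes=10, n_pairs=8))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
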