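import numpy as np
import pytest
from hypothesis import settings

from sccluster import SimConfig, simulate_zinb_mixture

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """The standard planted-cluster fixture (seed 1)."""
    return simulate_zinb_mixture(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A lighter fixture for training-loop tests."""
    return simulate_zinb_mixture(SimConfig(n_cells=300, n_genes=100, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
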