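import numpy as np
import pytest

from cloneburst import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def sim_default():
    """One default simulated study (K=4, M=6, N=50, T=4, high expression)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim_tiny():
    """A small, fast-to-fit study for sampler plumbing tests."""
    return simulate_dataset(SimulationConfig(seed=2, N=10, T=2))
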