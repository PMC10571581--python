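import numpy as np
import pytest

from brachyidv import (
    SimulationConfig,
    default_beta_spec,
    reference_registry,
    snd_spec,
)


@pytest.fixture(scope="session")
def registry():
    return reference_registry()


@pytest.fixture(scope="session")
def beta_spec():
    return default_beta_spec()


@pytest.fixture(scope="session")
def snd():
    return snd_spec()


@pytest.fixture
def config():
    """Full-protocol simulation configuration with a fixed seed."""
    return SimulationConfig(seed=1234)


@pytest.fixture
def small_config():
    """Reduced-size configuration for fast unit tests."""
    return SimulationConfig(n_sims_per_dose=2000, n_replicates=5, seed=99)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
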