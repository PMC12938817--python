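import numpy as np
import pytest

from pulsegate import (
    NoiseSpec,
    SimulationConfig,
    default_spec,
    simulate_trialset,
)


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture
def small_config():
    """A quick-to-simulate configuration for unit tests."""
    return SimulationConfig(n_trials=12, seed=7)


@pytest.fixture
def noise_free_config():
    return SimulationConfig(n_trials=8, seed=3, noise=NoiseSpec(rms_uv=0.0))


@pytest.fixture(scope="session")
def default_trialset():
    """One 100-trial simulation at the default study conditions (cached)."""
    return simulate_trialset(SimulationConfig(n_trials=100, seed=11))
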