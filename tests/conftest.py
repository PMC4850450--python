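import numpy as np
import pytest

from nirsnet import SimulationConfig, simulate_recording


@pytest.fixture(scope="session")
def small_config():
    """A light cohort configuration for fast pipeline tests."""
    return SimulationConfig(n_subjects=3, n_trials_per_case=4, seed=11)


@pytest.fixture(scope="session")
def small_recording(small_config):
    return simulate_recording(small_config, "S01", "spontaneous")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
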