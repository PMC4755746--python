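import numpy as np
import pytest

from tactilenp import periphery, stimulus


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: deterministic and
    # independent of test execution order
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def afferent_population():
    """Default 14 RA / 4 PC jittered population, shared across tests."""
    return periphery.make_population(seed=7)


@pytest.fixture(scope="session")
def noise_trace():
    return stimulus.make_bandpass_noise(50, 800, 20.0, 1.0, seed=21)
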