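import numpy as np
import pytest

import roadproxy as rp


@pytest.fixture(scope="session")
def small_landscape():
    return rp.generate_landscape(seed=1, n_villages=6)


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free exposure parameters for exact oracle comparisons."""
    return rp.ExposureModelParams(noise_sigma_log=0.0, seed=7)


@pytest.fixture(scope="session")
def default_params():
    return rp.ExposureModelParams(seed=7)


@pytest.fixture(scope="session")
def small_traces(small_landscape, default_params):
    return rp.simulate_traces(small_landscape, default_params,
                              n_participants=5, minutes_per_participant=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
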