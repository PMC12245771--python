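import numpy as np
import pytest

from ivim_habitat.dwi import DEFAULT_PROTOCOL
from ivim_habitat.ivim import fit_volume
from ivim_habitat.phantom import default_phantom_config, make_ivim_phantom


@pytest.fixture(scope="session")
def protocol():
    return DEFAULT_PROTOCOL


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Four-habitat block phantom without noise, plus its fitted maps."""
    config = default_phantom_config(sigma=0.0, seed=0)
    dwi, mask, truth = make_ivim_phantom(config)
    maps = fit_volume(dwi, mask)
    return config, dwi, mask, truth, maps


@pytest.fixture(scope="session")
def snr50_phantom():
    """Same layout under Rician noise at SNR(b=0) = 50 (sigma = S0/50)."""
    config = default_phantom_config(sigma=20.0, seed=7)
    dwi, mask, truth = make_ivim_phantom(config)
    maps = fit_volume(dwi, mask)
    return config, dwi, mask, truth, maps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
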