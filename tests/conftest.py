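import numpy as np
import pytest

from gaitstress import simulate_walker
from gaitstress.simulate import WalkerParams


@pytest.fixture(scope="session")
def noiseless_walker():
    """10+ gait cycles at 1.1 s stride, no noise, no bias."""
    params = WalkerParams(stride_time=1.1, duration=14.0, noise_sd=0.0, seed=7)
    return simulate_walker(params)


@pytest.fixture(scope="session")
def noisy_walker():
    """Same walker with 2 px Gaussian keypoint noise."""
    params = WalkerParams(stride_time=1.1, duration=14.0, noise_sd=2.0, seed=7)
    return simulate_walker(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
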