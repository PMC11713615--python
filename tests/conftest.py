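import numpy as np
import pytest

from isingnet import EffectiveNetwork, SpikeRaster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_net(rng):
    """Small random network with moderate couplings."""
    N = 5
    J = rng.normal(0.0, 0.3, (N, N))
    H = rng.normal(0.0, 0.3, N)
    return EffectiveNetwork(J=J, H=H)


@pytest.fixture
def small_raster(rng):
    states = rng.choice([-1, 1], size=(5, 200))
    return SpikeRaster(states=states, tau=0.05)
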