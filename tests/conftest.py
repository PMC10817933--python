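import numpy as np
import pytest

from temporal_deffuant import StaticNetwork, generate_er


@pytest.fixture
def triangle():
    return StaticNetwork(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def small_er():
    return generate_er(200, 10, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
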