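import numpy as np
import pytest

from sorn import SornParams, initialize_network


@pytest.fixture
def small_params():
    """A 20-neuron network dense enough to exercise every mechanism."""
    return SornParams(n_excitatory=20, p_ee_init=0.25, seed=7)


@pytest.fixture
def small_state(small_params):
    return initialize_network(small_params,
                              np.random.default_rng(small_params.seed))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
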