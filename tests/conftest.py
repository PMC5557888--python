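import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture
def small_system():
    """A modest random multi-cell system for statistical checks."""
    from protocell import Params, initialize_system
    params = Params(V=20, N=200)
    state = initialize_system(params, np.random.default_rng(5))
    return state, params
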