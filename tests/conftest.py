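import numpy as np
import pytest

from songseed import NifParams, HvcParams


@pytest.fixture
def nif_params():
    return NifParams()


@pytest.fixture
def small_nif_params():
    """A 5-neuron instance for oracle comparisons."""
    return NifParams(n_neurons=5, n_inputs=5)


@pytest.fixture
def fast_hvc_params():
    """Premotor parameters with a short protocol for structural tests."""
    return HvcParams(n_trials=300)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
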