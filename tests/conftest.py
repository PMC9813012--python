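import numpy as np
import pytest

from comodal import ModelParams, StimulusParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stim_params():
    return StimulusParams()


@pytest.fixture
def small_params():
    """A reservoir small enough for brute-force checking."""
    return ModelParams(N=40, S=10, p=0.5, I=4, O=3, alpha=10.0)
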