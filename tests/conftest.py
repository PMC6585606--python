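import numpy as np
import pytest
from hypothesis import settings

from limbselect import AGE_PRESETS, ModelParameters

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(params=list(AGE_PRESETS))
def preset(request):
    return AGE_PRESETS[request.param]


@pytest.fixture
def noise_free_params():
    """14mo inhibition structure with the noise switched off."""
    return ModelParameters(c_p=0.5, c_np=3.5, noise_strength=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
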