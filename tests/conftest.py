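import numpy as np
import pytest

from hfobench.background import high_hf_model, low_hf_model
from hfobench.events import make_default_dictionary

FS = 2048.0


@pytest.fixture(scope="session")
def dictionary():
    return make_default_dictionary(seed=0, fs=FS)


@pytest.fixture(scope="session")
def low_model():
    return low_hf_model()


@pytest.fixture(scope="session")
def high_model():
    return high_hf_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
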