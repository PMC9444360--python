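import numpy as np
import pytest

from lomaxshape import LomaxParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def params():
    return LomaxParams(shape=2.0, scale=2.0)
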