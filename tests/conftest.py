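import numpy as np
import pytest

from flthts import DEFAULT_IRF, IRFModel, TimeGrid


@pytest.fixture
def irf():
    return DEFAULT_IRF


@pytest.fixture
def delta_irf():
    return IRFModel(shape="delta", center=0.0, grid=TimeGrid(0.0, 0.25, 200))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
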