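import numpy as np
import pytest

from fragdisp.geometry import build_grid
from fragdisp.model import ModelParams


@pytest.fixture
def small_grid():
    """A cheap periodic tile (8 x 14 nodes)."""
    return build_grid(0.4, 0.05)


@pytest.fixture
def params():
    return ModelParams(n=5, beta=380.0, delta=36.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
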