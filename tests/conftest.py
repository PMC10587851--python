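import numpy as np
import pytest
from hypothesis import settings

from szest.field_model import build_neighbor_graph, make_grid

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def graph(grid):
    return build_neighbor_graph(grid, weight=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
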