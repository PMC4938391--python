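import numpy as np
import pytest

from tnlm import make_grid_mesh, standardize, TimeSeriesField


@pytest.fixture
def grid10():
    return make_grid_mesh(10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_standardized(rng):
    """Factory for standardized random fields."""

    def make(n_vertices, T):
        return standardize(
            TimeSeriesField(data=rng.standard_normal((n_vertices, T)))
        )

    return make
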