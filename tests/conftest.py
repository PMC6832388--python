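import numpy as np
import pytest

from greencities import synthetic


@pytest.fixture(scope="session")
def small_world():
    """An 80 x 80, 8-year synthetic world shared by read-only tests."""
    return synthetic.make_world(seed=42, ny=80, nx=80, n_years=8, n_cities=25)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture()
def unit_grid():
    """Edges of a 10 x 10 one-degree grid centered on the equator."""
    edges = np.linspace(-5.0, 5.0, 11)
    return edges, edges.copy()
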