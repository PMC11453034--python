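import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cdbme import ObservableBlock, gen_problem

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_obs_block():
    """Two conformers predicting 0 and 1 for one observable measured at 1."""
    return ObservableBlock("CS", [1.0], [1.0], [[0.0], [1.0]])


@pytest.fixture
def small_problem():
    """A 20-conformer synthetic problem with all three observable types."""
    return gen_problem(20, n_cd=15, n_saxs=12, n_cs=9, seed=77)


def random_simplex(rng, n):
    return rng.dirichlet(np.ones(n))
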