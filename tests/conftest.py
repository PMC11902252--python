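import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lmalign import Assembly, center_assembly, make_ladder_assembly

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ladder4():
    """A centered 4-chain, 6-point jittered ladder."""
    return make_ladder_assembly(4, 6, jitter_sd=0.3, seed=7)


@pytest.fixture
def random_assembly(rng):
    """A generic (non-symmetric) centered assembly, N=3, n=5."""
    a = Assembly(coords=rng.normal(scale=5.0, size=(3, 5, 3)), chain_ids=("A", "B", "C"))
    return center_assembly(a)[0]
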