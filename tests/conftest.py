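import numpy as np
import pytest

from cortimat.scheme import make_scheme


@pytest.fixture(scope="session")
def study_scheme():
    """The study's acquisition geometry: 32 directions at b=750 with one b0,
    64 directions at b=2500 with four b0s."""
    return make_scheme(32, 64, 1, 4, seed=1)


@pytest.fixture(scope="session")
def small_scheme():
    """A reduced two-shell scheme for fast tests."""
    return make_scheme(8, 12, 1, 2, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_unit_vector(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)
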