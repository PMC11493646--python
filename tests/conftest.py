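import numpy as np
import pytest

from hetkv import ChannelComposition, load_fixture


@pytest.fixture(scope="session")
def ntype_rates():
    return load_fixture("KV14_NTYPE_LIKE").rates


@pytest.fixture(scope="session")
def ctype_rates():
    return load_fixture("KV14_DN_CTYPE_LIKE").rates


@pytest.fixture(scope="session")
def plain_rates():
    return load_fixture("KV11_LIKE").rates


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


def all_compositions():
    comps = [ChannelComposition.plain()]
    comps += [ChannelComposition.n_type(n) for n in range(1, 5)]
    comps += [ChannelComposition.c_type(m) for m in range(1, 5)]
    return comps


def interior_gating_state(rng):
    """A random (q, n, h) strictly inside the gating simplex."""
    q = 0.05 + 0.9 * rng.random()
    x = rng.dirichlet([1.0, 1.0, 1.0])
    # keep away from the simplex boundary
    x = 0.9 * x + 0.1 / 3.0
    return np.array([q, x[1], x[2]])
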