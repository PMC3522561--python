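import numpy as np
import pytest

from odesd import make_fixture

try:
    from hypothesis import settings

    settings.register_profile("ci", max_examples=25, derandomize=True, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def mm():
    """Michaelis–Menten fixture with its compiled model."""
    fx = make_fixture("michaelis_menten")
    return fx, fx.compile()


@pytest.fixture(scope="session")
def decay():
    fx = make_fixture("linear_decay")
    return fx, fx.compile()


@pytest.fixture(scope="session")
def robertson():
    fx = make_fixture("robertson")
    return fx, fx.compile()


@pytest.fixture(scope="session")
def repressilator():
    fx = make_fixture("repressilator_like")
    return fx, fx.compile()


@pytest.fixture(scope="session")
def random_net():
    fx = make_fixture("random_massaction", seed=7, n=5)
    return fx, fx.compile()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
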