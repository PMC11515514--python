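import numpy as np
import pytest

from molnp.np_core import ContextSet, TargetSet, make_cnp, make_lnp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cnp(rng):
    return make_cnp(3, rng, r_dim=16, z_dim=8, width=16)


@pytest.fixture
def small_lnp(rng):
    return make_lnp(3, rng, r_dim=16, z_dim=8, width=16)


@pytest.fixture
def toy_task(rng):
    x = rng.normal(size=(30, 3))
    y = x @ np.array([1.0, -0.5, 0.2]) + 0.1 * rng.normal(size=30)
    return x, y


@pytest.fixture
def toy_context(toy_task):
    x, y = toy_task
    return ContextSet(x[:20], y[:20])


@pytest.fixture
def toy_targets(toy_task):
    x, y = toy_task
    return TargetSet(x[20:], y[20:])
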