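import numpy as np
import pytest

from intervalbayes import FAST_QUAD, ObserverParams, PriorSpec
from intervalbayes.models import Model


@pytest.fixture(scope="session")
def prior() -> PriorSpec:
    return PriorSpec()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def fast_quad():
    return FAST_QUAD


def make_params(model=Model.BLS, w_m=0.1, w_p=0.08, **kw) -> ObserverParams:
    return ObserverParams(Model(model), w_m=w_m, w_p=w_p, **kw)
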