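import numpy as np
import pytest

from spinhop import build_uracil_lvc_model, build_two_state_crossing


@pytest.fixture(scope="session")
def uracil_model():
    return build_uracil_lvc_model()


@pytest.fixture(scope="session")
def uracil_model_no_soc(uracil_model):
    return uracil_model.without_soc()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def two_state():
    return build_two_state_crossing(slope=0.01, coupling=2e-3, mass=2000.0)
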