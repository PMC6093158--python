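import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rangedyn import (
    DynamicsParams,
    NeighborhoodSpec,
    load_reference_habitat_model,
    make_fixture,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: posterior medians of the published transition-model fit — the generating
#: values for every parameter-recovery simulation
REFERENCE_PARAMS = DynamicsParams(
    phi0=-0.04, phi_d=5.94, phi_h=0.50, gam0=-1.34, gam_d=8.28, gam_h=0.64
)


@pytest.fixture(scope="session")
def reference_model():
    return load_reference_habitat_model()


@pytest.fixture(scope="session")
def reference_params():
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def fixture_bundle():
    return make_fixture()


@pytest.fixture(scope="session")
def dispersal_25_sq():
    return NeighborhoodSpec(radius_km=25, weight_exponent=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
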