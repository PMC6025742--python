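import pytest
from hypothesis import HealthCheck, settings

from nursedim import CareStandard, ModelParameters, hsj_eight_days

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standard() -> CareStandard:
    return CareStandard()


@pytest.fixture(scope="session")
def case():
    return hsj_eight_days()


@pytest.fixture()
def default_params() -> ModelParameters:
    return ModelParameters()
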