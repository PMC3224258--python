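import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clamp_params():
    from ciliadyn import ClampModelParams

    return ClampModelParams()


@pytest.fixture(scope="session")
def coupled_params():
    from ciliadyn import CoupledModelParams

    return CoupledModelParams()
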