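import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def ae_model():
    from rnaae import fmrp_fixture

    return fmrp_fixture("AE")


@pytest.fixture(scope="session")
def wt_model():
    from rnaae import fmrp_fixture

    return fmrp_fixture("WT")
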