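import pytest
from hypothesis import HealthCheck, settings

from drugrec.synthkb import demo_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_kb():
    kb, _patients = demo_fixture()
    return kb


@pytest.fixture(scope="session")
def fixture_patients():
    _kb, patients = demo_fixture()
    return {p.id: p for p in patients}
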