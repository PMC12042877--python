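import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def and_circuit():
    from asekit import make_fixture

    return make_fixture("fig2_AND")


@pytest.fixture
def or_circuit():
    from asekit import make_fixture

    return make_fixture("fig2_OR")


@pytest.fixture
def fourinput_circuit():
    from asekit import make_fixture

    return make_fixture("fig2_fourinput")
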