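import pytest
from hypothesis import HealthCheck, settings

from flowbed import doe, rtd

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def inserts():
    return rtd.builtin_inserts()


@pytest.fixture
def hc3(inserts):
    return inserts["HC3"]


@pytest.fixture
def cl1(inserts):
    return inserts["CL1"]


@pytest.fixture
def ethanol():
    return rtd.ETHANOL


@pytest.fixture
def space():
    return doe.DesignSpace.default()
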