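import pytest
from hypothesis import HealthCheck, settings

from toxvoi import load_scenario

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fatal_s1():
    return load_scenario("fatal-s1")


@pytest.fixture(scope="session")
def fatal_s2():
    return load_scenario("fatal-s2")


@pytest.fixture(scope="session")
def fatal_s3():
    return load_scenario("fatal-s3")


@pytest.fixture(scope="session")
def acute_s1():
    return load_scenario("acute-s1")


@pytest.fixture(scope="session")
def test_a(fatal_s1):
    return fatal_s1.tests[0]


@pytest.fixture(scope="session")
def test_b(fatal_s1):
    return fatal_s1.tests[1]
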