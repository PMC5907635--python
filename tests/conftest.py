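import pytest
from hypothesis import HealthCheck, settings

from oabcea import make_default_paramset, make_toy_paramset

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle():
    """Full 9-drug 5-level parameter set with its generating truth (read-only)."""
    return make_default_paramset(seed=1)


@pytest.fixture(scope="session")
def default_params(default_bundle):
    return default_bundle[0]


@pytest.fixture(scope="session")
def truth(default_bundle):
    return default_bundle[1]


@pytest.fixture()
def params(default_params):
    """Mutable copy of the default parameter set."""
    return default_params.copy()


@pytest.fixture()
def toy_params():
    """Reduced 2-level, 12-cycle parameter set (fresh copy per test)."""
    return make_toy_paramset(seed=1)
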