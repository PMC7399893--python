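import copy

import pytest
from hypothesis import HealthCheck, settings

import clts_cba as cba

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def _base_params():
    return cba.load_default_parameters()


@pytest.fixture()
def params(_base_params):
    """A fresh copy of the packaged base-case calibration per test."""
    return copy.deepcopy(_base_params)


@pytest.fixture(scope="session")
def base_result(_base_params):
    """Base-scenario run of the packaged calibration (read-only)."""
    return cba.run_scenario(_base_params)
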