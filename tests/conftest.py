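import pytest
from hypothesis import HealthCheck, settings

from drscreen import load_parameters

settings.register_profile(
    "unit",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("unit")

_CACHE = {}


def _params(setting):
    if setting not in _CACHE:
        _CACHE[setting] = load_parameters(setting=setting)
    return _CACHE[setting].copy()


@pytest.fixture
def rural_params():
    return _params("rural")


@pytest.fixture
def urban_params():
    return _params("urban")
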