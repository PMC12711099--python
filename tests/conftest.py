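import pytest
from hypothesis import HealthCheck, settings

from copdcem.model import default_model_inputs
from copdcem.parameters import default_parameters

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def ps():
    """A fresh default parameter set (mutable per test)."""
    return default_parameters()


@pytest.fixture(scope="session")
def inputs():
    """Default synthetic external inputs for the 60-month horizon."""
    return default_model_inputs(default_parameters())
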