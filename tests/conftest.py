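import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from megafund.config import bundled_config_path, load_analytic_cases

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table2_cases():
    """The twelve bundled worked parameter sets."""
    return load_analytic_cases(bundled_config_path("table2.yaml"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
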