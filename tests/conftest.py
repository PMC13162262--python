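import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eddycalc.carbonate import solve_state

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# deployment background conditions used throughout
ALK = 2650.0
PH = 8.04
TEMP = 25.0
SAL = 38.0


@pytest.fixture(scope="session")
def baseline_state():
    """Background seawater state of the study deployments."""
    return solve_state(ALK, TEMP, SAL, pH=PH)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200918)
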