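import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bottlepath as bp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Reference landscape of the phase diagram (r00, r10, r01, r11).
REFERENCE_LANDSCAPE = bp.FitnessLandscape(r00=0.2, r10=0.35, r01=0.9, r11=1.0)
REFERENCE_DELTA = 1.3


@pytest.fixture(scope="session")
def landscape() -> bp.FitnessLandscape:
    return REFERENCE_LANDSCAPE


@pytest.fixture(scope="session")
def delta() -> float:
    return REFERENCE_DELTA


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230202)
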