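import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import esynthesis as es

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def asthma_table() -> es.DoseResponseTable:
    """The built-in paracetamol-asthma cohort (5 dose groups, 299 events)."""
    return es.paracetamol_asthma_table()


@pytest.fixture
def published_theta() -> tuple[float, float]:
    """Published exponential parameters (alpha, beta) of the worked example."""
    return (1.01266e-3, 4.17805e-3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
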