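import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clpm_scrutiny import StudyRecord, builtin_table1

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    return builtin_table1()


@pytest.fixture
def example_record():
    """A study-like record with a plausible, strictly PD correlation matrix."""
    return StudyRecord(
        effect_id="11.1", n=542,
        r_p1p2=0.5, r_p1e1=0.4, r_p1e2=0.3,
        r_p2e1=0.35, r_p2e2=0.45, r_e1e2=0.6,
        predictor_name="Depression", waves=(1, 2), original_b=0.11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
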