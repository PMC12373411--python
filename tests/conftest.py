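import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_cfg():
    """A small, fast cohort used by unit tests."""
    from kinwell import CohortConfig

    return CohortConfig(
        n_participants=6,
        n_survey_completers=4,
        segment_duration_s=10.0,
        sampling_hz=25.0,
        seed=11,
    )
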