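import pytest
from hypothesis import HealthCheck, settings

from t2demu.cohort_design import enumerate_design
from t2demu.evaluation_pipeline import StudyConfig, run_full_study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def full_design():
    """The complete factorial design (46,170 subject specs)."""
    return enumerate_design()


@pytest.fixture(scope="session")
def default_study():
    """The desk-scale default study: 5,000-subject subsample, seed 1.

    Shared across the acceptance and importance tests so the expensive
    forest fit and permutation analyses run once per session.
    """
    return run_full_study(StudyConfig())
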