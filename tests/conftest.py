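import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from agile_frailty.domain import AGILE_ITEMS, AgileResponse
from agile_frailty.synthetic import CohortConfig, generate_cohort_frame


def make_response(**overrides):
    """A complete all-'no' AGILE response with selected answers overridden."""
    answers = {item: False for item in AGILE_ITEMS}
    answers.update(overrides)
    return AgileResponse(**answers)


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-subject default-configured cohort shared across tests."""
    return generate_cohort_frame(CohortConfig(n_subjects=2000, seed=7))


@pytest.fixture(scope="session")
def large_cohort():
    """The 100,000-subject calibration cohort (generated once per session)."""
    return generate_cohort_frame(CohortConfig(n_subjects=100_000, seed=2026))
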