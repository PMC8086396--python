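import numpy as np
import pytest

from camdexds.scoring import (
    InterviewRecord,
    default_codification,
    score_cohort,
)
from camdexds.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def codification():
    return default_codification()


@pytest.fixture
def make_record(codification):
    """Factory for a valid record with a constant response level everywhere."""

    def _make(level=0, overrides=None, **kwargs):
        responses = {it.item_id: level for it in codification}
        if overrides:
            responses.update(overrides)
        defaults = dict(
            participant_id="P001",
            age=45,
            sex="female",
            id_level="mild",
            mental_health_flag=False,
            diagnostic_group="asymptomatic",
        )
        defaults.update(kwargs)
        return InterviewRecord(responses=responses, **defaults)

    return _make


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across tests (seed 11)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_scored(default_cohort):
    return score_cohort(default_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
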