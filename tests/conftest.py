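import pytest

from esbi.instruments import EpisodeReport, ResponseRecord
from esbi.synthetic import CohortSpec, generate_cohort, paper_flow_fixture


@pytest.fixture(scope="session")
def fixture_records():
    """The deterministic published-flow fixture (172 participants)."""
    return paper_flow_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded synthetic cohort shared across tests."""
    return generate_cohort(CohortSpec(n=300, seed=11))


@pytest.fixture
def drinker_record():
    """One fully valid hazardous-range drinker record."""
    return ResponseRecord(
        participant_id="p1",
        gender="male",
        age_years=42,
        postcode="2300",
        drank_past_12m=True,
        audit_items=(3, 2, 2, 1, 0, 0, 1, 0, 0, 2),
        episode=EpisodeReport(max_drinks=10.0, duration_hours=4.0, weight_kg=80.0),
        ldq_items=(0, 1, 2, 3, 0, 1, 2, 3, 1, 2),
        trauma_items=(1, 0, 1, 0, 0),
    )


@pytest.fixture
def nondrinker_record():
    return ResponseRecord(
        participant_id="p2",
        gender="female",
        age_years=60,
        postcode="2300",
        drank_past_12m=False,
    )
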