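"""Synthetic respondents and participant-flow records.

The generator emits item-level response records together with flow-event
records so every other module is testable without any real data.  Defaults
emulate the observed recruitment episode of a hospital-outpatient screening
pilot: 172 approached, a 62.8% consent rate, a 93.4% completion rate, and a
15/43/33/8 split of completers over the four screening categories
(nondrinker / screen-negative / hazardous-harmful / possible dependence).

The key construction: each drinker's AUDIT items 1-3 are drawn uniformly
from the exact set of score triples whose sum falls in the target
category's AUDIT-C range (found by enumerating all 5^3 = 125 triples), so
the intended category always round-trips through scoring + classification.
Items 4-10, the LDQ, the trauma screen and the heaviest episode are sampled
from category-conditioned distributions that couple monotonically with
severity; these are synthetic choices, not empirical estimates.

``paper_flow_fixture`` is a deterministic flow-event list whose node counts
equal the published participant-flow figure, used for desk-scale checks of
the feasibility summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ConfigError
from .feasibility import FlowEventRecord
from .instruments import EpisodeReport, ResponseRecord
from .screening import ScreeningCategory

__all__ = ["CohortSpec", "auditc_triples", "generate_cohort", "paper_flow_fixture"]

DRINKER_CATEGORIES = (
    ScreeningCategory.NEGATIVE,
    ScreeningCategory.HAZARDOUS_HARMFUL,
    ScreeningCategory.POSSIBLE_DEPENDENCE,
)

# AUDIT-C score range per category (inclusive)
_AUDITC_RANGE = {
    ScreeningCategory.NEGATIVE: (0, 4),
    ScreeningCategory.HAZARDOUS_HARMFUL: (5, 9),
    ScreeningCategory.POSSIBLE_DEPENDENCE: (10, 12),
}

# Category-conditioned option distributions for AUDIT items 4-8 (5 options),
# items 9-10 (3 options), and LDQ items (4 options): synthetic severity
# coupling, not empirical estimates.
_AUDIT_TAIL_P = {
    ScreeningCategory.NEGATIVE: ([0.75, 0.17, 0.06, 0.02, 0.0], [0.92, 0.06, 0.02]),
    ScreeningCategory.HAZARDOUS_HARMFUL: ([0.35, 0.30, 0.20, 0.10, 0.05], [0.70, 0.20, 0.10]),
    ScreeningCategory.POSSIBLE_DEPENDENCE: ([0.10, 0.20, 0.30, 0.25, 0.15], [0.40, 0.30, 0.30]),
}
_LDQ_P = {
    ScreeningCategory.NEGATIVE: [0.90, 0.08, 0.02, 0.0],
    ScreeningCategory.HAZARDOUS_HARMFUL: [0.60, 0.25, 0.10, 0.05],
    ScreeningCategory.POSSIBLE_DEPENDENCE: [0.35, 0.30, 0.20, 0.15],
}
_TRAUMA_P = {
    ScreeningCategory.NEGATIVE: 0.10,
    ScreeningCategory.HAZARDOUS_HARMFUL: 0.25,
    ScreeningCategory.POSSIBLE_DEPENDENCE: 0.40,
}
# Heaviest-occasion drinks range per category (uniform integer draw)
_EPISODE_DRINKS = {
    ScreeningCategory.NEGATIVE: (1, 4),
    ScreeningCategory.HAZARDOUS_HARMFUL: (5, 18),
    ScreeningCategory.POSSIBLE_DEPENDENCE: (8, 28),
}


@lru_cache(maxsize=None)
def auditc_triples(category: ScreeningCategory) -> tuple[tuple[int, int, int], ...]:
    """All item-1-3 score triples whose sum lies in the category's range.

    Enumerated over the full 5 x 5 x 5 grid of option scores (each item
    scores 0-4).
    """
    lo, hi = _AUDITC_RANGE[category]
    return tuple(
        t for t in itertools.product(range(5), repeat=3) if lo <= sum(t) <= hi
    )


@dataclass
class CohortSpec:
    """Conditions for one synthetic recruitment episode.

    ``n`` is the number of outpatients approached.  Mixture and probability
    defaults reproduce the observed study conditions: consent 108/172,
    pre-consent ineligibility 2/172, post-consent ineligibility 2/108,
    completion 99/106 with a 3:4 technical/called-away split, completer
    categories 15/43/33/8 over 99, follow-up invitation (drank in the past
    4 weeks) 32/43, 30/33, 7/8 and follow-up completion 26/32, 22/30, 4/7
    by drinker category.
    """

    n: int = 172
    seed: int = 0
    category_mixture: dict[ScreeningCategory, float] = field(
        default_factory=lambda: {
            ScreeningCategory.NONDRINKER_12M: 15 / 99,
            ScreeningCategory.NEGATIVE: 43 / 99,
            ScreeningCategory.HAZARDOUS_HARMFUL: 33 / 99,
            ScreeningCategory.POSSIBLE_DEPENDENCE: 8 / 99,
        }
    )
    male_prob: float = 53 / 99
    age_group_mixture: tuple[float, float, float] = (33 / 99, 32 / 99, 34 / 99)
    consent_prob: float = 108 / 172
    ineligible_at_approach_prob: float = 2 / 172
    ineligible_after_consent_prob: float = 2 / 108
    completion_prob: float = 99 / 106
    technical_noncompletion_prob: float = 3 / 7
    invited_followup_prob: dict[ScreeningCategory, float] = field(
        default_factory=lambda: {
            ScreeningCategory.NEGATIVE: 32 / 43,
            ScreeningCategory.HAZARDOUS_HARMFUL: 30 / 33,
            ScreeningCategory.POSSIBLE_DEPENDENCE: 7 / 8,
        }
    )
    followup_completion_prob: dict[ScreeningCategory, float] = field(
        default_factory=lambda: {
            ScreeningCategory.NEGATIVE: 26 / 32,
            ScreeningCategory.HAZARDOUS_HARMFUL: 22 / 30,
            ScreeningCategory.POSSIBLE_DEPENDENCE: 4 / 7,
        }
    )

    def validate(self) -> None:
        probs = list(self.category_mixture.values())
        if any(not 0 <= p <= 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError("category mixture must be probabilities summing to 1")
        if set(self.category_mixture) != set(ScreeningCategory):
            raise ConfigError("category mixture must cover all four screening categories")
        if abs(sum(self.age_group_mixture) - 1.0) > 1e-9:
            raise ConfigError("age-group mixture must sum to 1")
        for name in (
            "male_prob",
            "consent_prob",
            "ineligible_at_approach_prob",
            "ineligible_after_consent_prob",
            "completion_prob",
            "technical_noncompletion_prob",
        ):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.consent_prob + self.ineligible_at_approach_prob > 1:
            raise ConfigError("consent and approach-ineligibility probabilities exceed 1")
        if self.n < 0:
            raise ConfigError("n must be non-negative")


def _sample_age(rng: np.random.Generator, mixture: tuple[float, float, float]) -> int:
    group = rng.choice(3, p=list(mixture))
    lo, hi = ((18, 34), (35, 54), (55, 85))[group]
    return int(rng.integers(lo, hi + 1))


def _sample_items(rng: np.random.Generator, p: list[float], n_items: int) -> list[int]:
    return [int(rng.choice(len(p), p=p)) for _ in range(n_items)]


def _drinker_record(
    rng: np.random.Generator,
    pid: str,
    gender: str,
    age: int,
    category: ScreeningCategory,
    consumed_4wk: bool,
) -> ResponseRecord:
    triples = auditc_triples(category)
    first3 = list(triples[int(rng.integers(len(triples)))])
    tail_p5, tail_p3 = _AUDIT_TAIL_P[category]
    audit = first3 + _sample_items(rng, tail_p5, 5) + _sample_items(rng, tail_p3, 2)
    lo, hi = _EPISODE_DRINKS[category]
    drinks = float(rng.integers(lo, hi + 1)) if consumed_4wk else 0.0
    weight_mu = 85.0 if gender == "male" else 72.0
    weight = float(max(45.0, rng.normal(weight_mu, 12.0)))
    episode = EpisodeReport(
        max_drinks=drinks,
        duration_hours=float(rng.uniform(1.0, 8.0)),
        weight_kg=round(weight, 1),
    )
    return ResponseRecord(
        participant_id=pid,
        gender=gender,
        age_years=age,
        postcode=f"2{rng.integers(100, 999)}",
        drank_past_12m=True,
        audit_items=tuple(audit),
        episode=episode,
        ldq_items=tuple(_sample_items(rng, _LDQ_P[category], 10)),
        trauma_items=tuple(int(rng.random() < _TRAUMA_P[category]) for _ in range(5)),
    )


def generate_cohort(
    spec: CohortSpec | None = None,
) -> tuple[list[ResponseRecord], list[FlowEventRecord]]:
    """Generate one synthetic recruitment episode.

    Returns item-level response records (completers only — interrupted or
    non-consenting patients leave no usable responses) and flow-event
    records for everyone approached.  Reproducible: identical spec and seed
    give identical output.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cats = list(spec.category_mixture.keys())
    cat_p = list(spec.category_mixture.values())

    responses: list[ResponseRecord] = []
    flow: list[FlowEventRecord] = []
    for i in range(spec.n):
        pid = f"S{i + 1:05d}"
        rec = FlowEventRecord(participant_id=pid)
        u = rng.random()
        if u < spec.ineligible_at_approach_prob:
            rec.eligible = False
            flow.append(rec)
            continue
        if u >= spec.ineligible_at_approach_prob + spec.consent_prob:
            flow.append(rec)  # refused
            continue
        rec.consented = True
        if rng.random() < spec.ineligible_after_consent_prob:
            rec.eligible = False
            flow.append(rec)
            continue
        if rng.random() >= spec.completion_prob:
            rec.noncompletion_reason = (
                "technical"
                if rng.random() < spec.technical_noncompletion_prob
                else "called_for_appointment"
            )
            flow.append(rec)
            continue
        rec.completed_esbi = True
        category = cats[int(rng.choice(len(cats), p=cat_p))]
        rec.category = category
        gender = "male" if rng.random() < spec.male_prob else "female"
        age = _sample_age(rng, spec.age_group_mixture)
        if category is ScreeningCategory.NONDRINKER_12M:
            responses.append(
                ResponseRecord(
                    participant_id=pid,
                    gender=gender,
                    age_years=age,
                    postcode=f"2{rng.integers(100, 999)}",
                    drank_past_12m=False,
                )
            )
            flow.append(rec)
            continue
        invited = rng.random() < spec.invited_followup_prob[category]
        rec.invited_followup = invited
        if invited:
            rec.completed_followup = rng.random() < spec.followup_completion_prob[category]
        # acceptability: a mild severity gradient over the 4 'useful' options
        rec.acceptability = {
            "feedback_useful": int(rng.choice(4, p=[0.25, 0.24, 0.30, 0.21])),
            "appeal": int(rng.choice(4, p=[0.14, 0.49, 0.36, 0.01])),
        }
        responses.append(
            _drinker_record(rng, pid, gender, age, category, invited)
        )
        flow.append(rec)
    return responses, flow


# ---------------------------------------------------------------------------
# deterministic published-flow fixture


def _fixture_block(
    start: int,
    count: int,
    **overrides,
) -> list[FlowEventRecord]:
    return [
        FlowEventRecord(participant_id=f"F{start + j:03d}", **overrides)
        for j in range(count)
    ]


def _assign_counts(values: list[int | None], counts: list[tuple[int | None, int]]) -> list[int | None]:
    out: list[int | None] = []
    for value, k in counts:
        out.extend([value] * k)
    return out


def paper_flow_fixture() -> list[FlowEventRecord]:
    """The published participant flow as a deterministic record list.

    Node counts: 172 approached = 108 consented + 62 refused + 2 ineligible;
    106 eligible after 2 post-consent exclusions; 7 noncompleters (3
    technical, 4 called away); 99 completers split 15/43/33/8 over the
    screening categories; 69 invited to follow-up of whom 52 completed
    (30 invited / 22 completed in the hazardous-harmful subgroup).
    Acceptability answers reproduce the published "feedback useful" and
    "appeal" crosstab columns (each with one missing answer in the
    hazardous-harmful column).
    """
    records: list[FlowEventRecord] = []
    i = 1
    records += _fixture_block(i, 2, consented=False, eligible=False)
    i += 2
    records += _fixture_block(i, 62, consented=False, eligible=True)
    i += 62
    records += _fixture_block(i, 2, consented=True, eligible=False)
    i += 2
    records += _fixture_block(i, 3, consented=True, noncompletion_reason="technical")
    i += 3
    records += _fixture_block(i, 4, consented=True, noncompletion_reason="called_for_appointment")
    i += 4
    records += _fixture_block(
        i, 15, consented=True, completed_esbi=True, category=ScreeningCategory.NONDRINKER_12M
    )
    i += 15

    # completer drinkers: (category, n, invited, followed-up, useful counts, appeal counts)
    plan = [
        (ScreeningCategory.NEGATIVE, 43, 32, 26, [11, 7, 13, 12], [11, 22, 10, 0]),
        (ScreeningCategory.HAZARDOUS_HARMFUL, 33, 30, 22, [6, 11, 10, 5], [0, 15, 17, 0]),
        (ScreeningCategory.POSSIBLE_DEPENDENCE, 8, 7, 4, [4, 2, 2, 0], [1, 4, 3, 0]),
    ]
    for category, n, invited, followed, useful_counts, appeal_counts in plan:
        block = _fixture_block(
            i, n, consented=True, completed_esbi=True, category=category
        )
        i += n
        useful = _assign_counts([], [(k, c) for k, c in enumerate(useful_counts)])
        useful += [None] * (n - len(useful))  # missing answers
        appeal = _assign_counts([], [(k, c) for k, c in enumerate(appeal_counts)])
        appeal += [None] * (n - len(appeal))
        for j, rec in enumerate(block):
            rec.invited_followup = j < invited
            rec.completed_followup = j < followed
            # a missing answer is an absent key
            rec.acceptability = {
                qid: ans
                for qid, ans in (("feedback_useful", useful[j]), ("appeal", appeal[j]))
                if ans is not None
            }
        records += block
    assert len(records) == 172
    return records
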