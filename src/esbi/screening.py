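"""AUDIT-C risk classification and trial eligibility.

Screening uses only the AUDIT-C consumption subscale (AUDIT items 1-3,
score 0-12), chosen over the full AUDIT to minimise assessment effects.
The four mutually exclusive categories:

================  ====================  ==============
category          rule                  trial eligible
================  ====================  ==============
nondrinker_12m    no alcohol in 12 mo   no
negative          AUDIT-C < 5           no
hazardous_harmful AUDIT-C 5-9           yes
possible_dependence AUDIT-C 10-12       no
================  ====================  ==============

The 5-point floor has high specificity with good sensitivity for hazardous
or harmful drinking; above 9 the probability of dependence is high enough
that brief intervention alone is unlikely to suffice, so those participants
are not trial-eligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .instruments import InstrumentScores, ResponseRecord, score_audit, score_record

__all__ = ["ScreeningCategory", "ScreeningResult", "classify", "screen_record", "screen_records"]

AUDIT_C_MIN_POSITIVE = 5  # minimum AUDIT-C for hazardous/harmful screen-positive
AUDIT_C_MAX_POSITIVE = 9  # above this, possible dependence


class ScreeningCategory(str, Enum):
    NONDRINKER_12M = "nondrinker_12m"
    NEGATIVE = "negative"
    HAZARDOUS_HARMFUL = "hazardous_harmful"
    POSSIBLE_DEPENDENCE = "possible_dependence"


@dataclass(frozen=True)
class ScreeningResult:
    category: ScreeningCategory
    scores: InstrumentScores | None  # absent only for nondrinker_12m
    trial_eligible: bool


def classify(drank_past_12m: bool, audit_c: int | None = None) -> ScreeningResult:
    """Map the 12-month gate and AUDIT-C score to a screening category.

    ``audit_c`` must be present iff ``drank_past_12m`` is true.  Exactly one
    category applies to every input; ``trial_eligible`` is true iff the
    category is hazardous/harmful.
    """
    if not drank_past_12m:
        if audit_c is not None:
            raise ValidationError("audit_c supplied for a participant gated out at 12 months")
        return ScreeningResult(ScreeningCategory.NONDRINKER_12M, None, False)
    if audit_c is None:
        raise ValidationError("audit_c required for participants who drank in the past 12 months")
    if isinstance(audit_c, bool) or not isinstance(audit_c, int) or not 0 <= audit_c <= 12:
        raise ValidationError(f"audit_c must be an integer in 0-12, got {audit_c!r}")
    if audit_c < AUDIT_C_MIN_POSITIVE:
        cat = ScreeningCategory.NEGATIVE
    elif audit_c <= AUDIT_C_MAX_POSITIVE:
        cat = ScreeningCategory.HAZARDOUS_HARMFUL
    else:
        cat = ScreeningCategory.POSSIBLE_DEPENDENCE
    return ScreeningResult(cat, None, cat is ScreeningCategory.HAZARDOUS_HARMFUL)


def screen_record(record: ResponseRecord) -> ScreeningResult:
    """Score a response record and classify it.

    Nondrinkers classify directly; drinkers are scored on all instruments
    and the AUDIT-C determines the category.
    """
    if not record.drank_past_12m:
        return classify(False)
    scores = score_record(record)
    base = classify(True, scores.audit_c)
    return ScreeningResult(base.category, scores, base.trial_eligible)


def screen_records(records: Iterable[ResponseRecord]) -> pd.DataFrame:
    """Batch screening: one row per participant.

    Columns: participant_id, audit_c (nullable), category, trial_eligible.
    """
    rows = []
    for rec in records:
        res = screen_record(rec)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "audit_c": res.scores.audit_c if res.scores else pd.NA,
                "category": res.category.value,
                "trial_eligible": res.trial_eligible,
            }
        )
    return pd.DataFrame(
        rows, columns=["participant_id", "audit_c", "category", "trial_eligible"]
    )
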