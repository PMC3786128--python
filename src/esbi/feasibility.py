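"""Feasibility summaries: recruitment, completion, acceptability, retention.

Summaries follow descriptive-statistics conventions for pilot feasibility
reporting: frequencies and percentages for discrete variables, medians with
25th/75th percentiles for continuous ones.  Percentages are computed from
their own counts under an explicit rounding rule (half-up; one decimal for
participant-flow percentages, integers for acceptability and retention
percentages).  Ratios with a zero denominator are reported as undefined,
never as 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .screening import ScreeningCategory

__all__ = [
    "FlowEventRecord",
    "CohortSummary",
    "round_half_up",
    "pct",
    "Ratio",
    "validate_flow_records",
    "recruitment_summary",
    "completion_rate",
    "retention_rate",
    "acceptability_table",
    "proportion_endorsing",
    "median_iqr",
    "summarize",
]

NONCOMPLETION_REASONS = ("technical", "called_for_appointment", "none")

# Post-completion acceptability questions (asked of drinkers only) with
# their ordered response options.
ACCEPTABILITY_QUESTIONS: dict[str, tuple[str, tuple[str, ...]]] = {
    "feedback_useful": (
        "Was the feedback on your drinking useful?",
        ("Very useful", "Quite useful", "Somewhat useful", "Not useful at all"),
    ),
    "appeal": (
        "Do you think this online intervention will appeal to people who attend this service?",
        ("Yes, all of them", "Yes, most of them", "Only some of them", "None of them"),
    ),
}


@dataclass
class FlowEventRecord:
    """One participant's passage through the recruitment/intervention flow.

    ``eligible`` means "not determined ineligible" (refusers are never
    assessed, so they carry ``eligible=True``).  ``category`` is present only
    for participants who completed the screening program.
    """

    participant_id: str
    approached: bool = True
    consented: bool = False
    eligible: bool = True
    completed_esbi: bool = False
    noncompletion_reason: str = "none"
    category: ScreeningCategory | None = None
    invited_followup: bool = False
    completed_followup: bool = False
    acceptability: dict[str, int | None] = field(default_factory=dict)
    followup: dict[str, int | None] = field(default_factory=dict)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (the convention behind printed tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Ratio:
    """count/denominator with its rounded percentage (None when undefined)."""

    count: int
    denominator: int
    pct: float | None

    def as_dict(self) -> dict:
        return {"count": self.count, "denominator": self.denominator, "pct": self.pct}


def pct(count: int, denominator: int, decimals: int = 1) -> Ratio:
    """A Ratio with half-up rounding; undefined (pct=None) on zero denominator."""
    if denominator == 0:
        return Ratio(count, 0, None)
    value = round_half_up(100.0 * count / denominator, decimals)
    if decimals == 0:
        value = int(value)
    return Ratio(count, denominator, value)


def validate_flow_records(records: Sequence[FlowEventRecord]) -> None:
    """Raise listing every record that violates the flow invariants."""
    offenders = []
    for r in records:
        problems = []
        if r.consented and not r.approached:
            problems.append("consented without being approached")
        if r.completed_esbi and not (r.consented and r.eligible):
            problems.append("completed without consent/eligibility")
        if r.completed_followup and not r.invited_followup:
            problems.append("completed follow-up without invitation")
        if r.noncompletion_reason not in NONCOMPLETION_REASONS:
            problems.append(f"unknown noncompletion reason {r.noncompletion_reason!r}")
        if r.completed_esbi and r.noncompletion_reason != "none":
            problems.append("completer carries a noncompletion reason")
        if r.category is not None and not r.completed_esbi:
            problems.append("screening category without completion")
        if problems:
            offenders.append(f"{r.participant_id}: " + "; ".join(problems))
    if offenders:
        raise ValidationError("invalid flow records:\n" + "\n".join(offenders))


def _eligible_consenting(records: Sequence[FlowEventRecord]) -> list[FlowEventRecord]:
    return [r for r in records if r.consented and r.eligible]


def recruitment_summary(records: Sequence[FlowEventRecord]) -> dict:
    """Counts and percentages for every recruitment/screening flow node.

    Flow percentages use one decimal.  The screening mix (noncompleted plus
    the four categories) is reported out of the eligible consenting
    participants; "unhealthy use" pools the hazardous/harmful and
    possible-dependence categories.
    """
    records = list(records)
    validate_flow_records(records)
    approached = [r for r in records if r.approached]
    n_app = len(approached)
    consented = [r for r in approached if r.consented]
    refused = [r for r in approached if not r.consented and r.eligible]
    inelig_pre = [r for r in approached if not r.consented and not r.eligible]
    inelig_post = [r for r in consented if not r.eligible]
    eligible = _eligible_consenting(records)
    n_elig = len(eligible)

    noncompleted = [r for r in eligible if not r.completed_esbi]
    by_cat = {
        cat: [r for r in eligible if r.category is cat] for cat in ScreeningCategory
    }
    unhealthy = (
        len(by_cat[ScreeningCategory.HAZARDOUS_HARMFUL])
        + len(by_cat[ScreeningCategory.POSSIBLE_DEPENDENCE])
    )
    summary = {
        "approached": n_app,
        "consented": pct(len(consented), n_app).as_dict(),
        "refused": pct(len(refused), n_app).as_dict(),
        "ineligible_at_approach": pct(len(inelig_pre), n_app).as_dict(),
        "ineligible_after_consent": pct(len(inelig_post), len(consented)).as_dict(),
        "eligible_consenting": n_elig,
        "screening": {
            "noncompleted": pct(len(noncompleted), n_elig).as_dict(),
            **{
                cat.value: pct(len(rs), n_elig).as_dict() for cat, rs in by_cat.items()
            },
        },
        "unhealthy_use": pct(unhealthy, n_elig).as_dict(),
    }
    return summary


def completion_rate(records: Sequence[FlowEventRecord]) -> dict:
    """Program-completion proportion with a reason breakdown for noncompleters.

    Reasons partition the noncompleters; reason percentages are integers
    out of the noncompleter count.
    """
    records = list(records)
    validate_flow_records(records)
    eligible = _eligible_consenting(records)
    completers = [r for r in eligible if r.completed_esbi]
    noncompleters = [r for r in eligible if not r.completed_esbi]
    reasons = {}
    for reason in NONCOMPLETION_REASONS[:-1]:
        k = sum(1 for r in noncompleters if r.noncompletion_reason == reason)
        if noncompleters:
            reasons[reason] = pct(k, len(noncompleters), 0).as_dict()
    return {
        "completed": pct(len(completers), len(eligible)).as_dict(),
        "noncompleted": pct(len(noncompleters), len(eligible)).as_dict(),
        "reasons": reasons,
    }


def retention_rate(
    records: Sequence[FlowEventRecord],
    subgroup: Callable[[FlowEventRecord], bool] | None = None,
) -> dict:
    """Follow-up completion among the invited, optionally within a subgroup.

    Integer percentage.  An empty invited set is flagged undefined rather
    than reported as 0%.
    """
    records = list(records)
    validate_flow_records(records)
    if subgroup is not None:
        records = [r for r in records if subgroup(r)]
    invited = [r for r in records if r.invited_followup]
    completed = [r for r in invited if r.completed_followup]
    ratio = pct(len(completed), len(invited), 0)
    out = ratio.as_dict()
    out["undefined"] = ratio.pct is None
    return out


def acceptability_table(
    records: Sequence[FlowEventRecord],
    questions: dict[str, tuple[str, tuple[str, ...]]] | None = None,
) -> pd.DataFrame:
    """Question x option x category crosstab with column percentages.

    Columns are the three drinker screening categories plus an all-drinkers
    column.  Percentages (integer, half-up) use the number of drinker
    completers in the category as denominator — the column "n" — so missing
    answers reduce the column sum below 100%.
    """
    questions = questions or ACCEPTABILITY_QUESTIONS
    records = list(records)
    validate_flow_records(records)
    drinker_cats = (
        ScreeningCategory.NEGATIVE,
        ScreeningCategory.HAZARDOUS_HARMFUL,
        ScreeningCategory.POSSIBLE_DEPENDENCE,
    )
    drinkers = [r for r in records if r.completed_esbi and r.category in drinker_cats]
    columns = {"all_drinkers": drinkers}
    columns.update({cat.value: [r for r in drinkers if r.category is cat] for cat in drinker_cats})

    rows = []
    for qid, (text, options) in questions.items():
        for opt_idx, opt in enumerate(options):
            row: dict = {"question": qid, "option": opt}
            for col, members in columns.items():
                n_col = len(members)
                k = sum(1 for r in members if r.acceptability.get(qid) == opt_idx)
                ratio = pct(k, n_col, 0)
                row[f"{col}_n"] = k
                row[f"{col}_pct"] = ratio.pct
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["column_totals"] = {col: len(members) for col, members in columns.items()}
    df.attrs["question_texts"] = {qid: text for qid, (text, _) in questions.items()}
    return df


def proportion_endorsing(
    records: Sequence[FlowEventRecord],
    question: str,
    option_indices: Iterable[int],
    category: ScreeningCategory | None = None,
) -> dict:
    """Share of a category's drinker completers endorsing any of the options.

    Denominator is the category completer count (missing answers included),
    matching how acceptability columns are reported.  Integer percentage.
    """
    records = [r for r in records if r.completed_esbi and r.category is not ScreeningCategory.NONDRINKER_12M]
    if category is not None:
        records = [r for r in records if r.category is category]
    opts = set(option_indices)
    k = sum(1 for r in records if r.acceptability.get(question) in opts)
    return pct(k, len(records), 0).as_dict()


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, 25th percentile, 75th percentile) by linear interpolation.

    The quartile convention (linear interpolation between order statistics)
    is explicit because published tables rarely state theirs; override by
    computing quantiles directly if another convention is needed.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("median_iqr requires a non-empty list")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("median_iqr requires finite values")
    med, q25, q75 = np.percentile(arr, [50, 25, 75], method="linear")
    return float(med), float(q25), float(q75)


@dataclass
class CohortSummary:
    """All feasibility summaries for one recruitment episode."""

    recruitment: dict
    completion: dict
    retention_overall: dict
    retention_hazardous_harmful: dict
    acceptability: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "recruitment": self.recruitment,
            "completion": self.completion,
            "retention": {
                "overall": self.retention_overall,
                "hazardous_harmful": self.retention_hazardous_harmful,
            },
            "acceptability": {
                "column_totals": self.acceptability.attrs.get("column_totals", {}),
                "rows": self.acceptability.to_dict(orient="records"),
            },
        }


def format_summary_tables(summary: "CohortSummary") -> str:
    """Aligned-text rendering of the flow, completion, retention and
    acceptability summaries."""

    def line(label: str, d: dict) -> str:
        p = d["pct"]
        ptxt = "undefined" if p is None else f"{p}%"
        return f"  {label:<28} {d['count']:>4}/{d['denominator']:<4} {ptxt}"

    rec = summary.recruitment
    parts = ["Participant flow", f"  approached: {rec['approached']}"]
    for key in ("consented", "refused", "ineligible_at_approach", "ineligible_after_consent"):
        parts.append(line(key, rec[key]))
    parts.append(f"  eligible consenting: {rec['eligible_consenting']}")
    parts.append("Screening mix (of eligible consenting)")
    for key, d in rec["screening"].items():
        parts.append(line(key, d))
    parts.append(line("unhealthy_use", rec["unhealthy_use"]))
    parts.append("Completion")
    parts.append(line("completed", summary.completion["completed"]))
    for reason, d in summary.completion["reasons"].items():
        parts.append(line(f"  {reason}", d))
    parts.append("Retention (follow-up)")
    parts.append(line("overall", summary.retention_overall))
    parts.append(line("hazardous/harmful", summary.retention_hazardous_harmful))
    parts.append("Acceptability (n and % of category column)")
    parts.append(summary.acceptability.to_string(index=False))
    return "\n".join(parts)


def summarize(records: Sequence[FlowEventRecord]) -> CohortSummary:
    """Compute every feasibility summary for a set of flow records."""
    return CohortSummary(
        recruitment=recruitment_summary(records),
        completion=completion_rate(records),
        retention_overall=retention_rate(records),
        retention_hazardous_harmful=retention_rate(
            records, lambda r: r.category is ScreeningCategory.HAZARDOUS_HARMFUL
        ),
        acceptability=acceptability_table(records),
    )
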