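"""Questionnaire instruments and their scoring.

The screening program administers, in page order: demographics, a 12-month
drinking gate, the 10-item Alcohol Use Disorders Identification Test (AUDIT),
a heaviest-drinking-episode report (drinks, duration, body weight), the
10-item Leeds Dependence Questionnaire (LDQ), and a 5-item trauma-history
screen.  Item texts, response options and per-option scores live in an
editable YAML definitions file (``data/instruments.yaml``); scoring functions
look scores up from those definitions, so wording changes never touch code.

Scoring conventions:

* AUDIT: items 1-8 scored 0-4, items 9-10 scored 0/2/4; total 0-40.  The
  AUDIT-C consumption subscale is the sum of items 1-3 (0-12).
* LDQ: 10 items scored 0-3; total 0-30.
* Trauma screen: 5 yes/no items; score = count of affirmatives (0-5).

Missing or out-of-range answers are validation errors naming the offending
item — nothing is imputed or prorated.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ConfigError, ValidationError

__all__ = [
    "ItemDef",
    "InstrumentDef",
    "EpisodeReport",
    "ResponseRecord",
    "InstrumentScores",
    "Violation",
    "load_instruments",
    "default_instruments",
    "score_audit",
    "score_ldq",
    "score_trauma",
    "score_record",
    "validate_record",
]

GENDERS = ("male", "female")
MIN_AGE_YEARS = 18

_EMAIL_RE = re.compile(r"^[^@\s]+@[^@\s]+\.[^@\s]+$")


@dataclass(frozen=True)
class ItemDef:
    """One questionnaire item: label, ordered options, per-option scores."""

    text: str
    options: tuple[str, ...]
    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.options) != len(self.scores):
            raise ConfigError(
                f"item {self.text!r}: {len(self.options)} options but {len(self.scores)} scores"
            )
        if any((not isinstance(s, int)) or s < 0 for s in self.scores):
            raise ConfigError(f"item {self.text!r}: option scores must be non-negative integers")


@dataclass(frozen=True)
class InstrumentDef:
    """An ordered set of items forming one instrument."""

    id: str
    name: str
    items: tuple[ItemDef, ...]
    placeholder: bool = False

    @property
    def n_items(self) -> int:
        return len(self.items)

    def max_total(self) -> int:
        return sum(max(item.scores) for item in self.items)


@dataclass(frozen=True)
class EpisodeReport:
    """Heaviest drinking occasion in the last 4 weeks, for BAC estimation.

    ``max_drinks`` is in Australian standard drinks (10 g ethanol each);
    ``duration_hours`` is the length of that occasion; ``weight_kg`` body
    weight.  ``max_drinks == 0`` permits any duration.
    """

    max_drinks: float
    duration_hours: float
    weight_kg: float


@dataclass
class ResponseRecord:
    """One participant's item-level answers plus demographics.

    Downstream instrument answers are ``None`` when the participant reported
    no alcohol in the past 12 months (the gate sends them straight to the
    thank-you page).
    """

    participant_id: str
    gender: str
    age_years: int
    postcode: str
    drank_past_12m: bool
    audit_items: tuple[int, ...] | None = None
    episode: EpisodeReport | None = None
    ldq_items: tuple[int, ...] | None = None
    trauma_items: tuple[int, ...] | None = None
    email: str | None = None


@dataclass(frozen=True)
class InstrumentScores:
    """Totals for a fully answered drinker record."""

    audit_total: int
    audit_c: int
    ldq_total: int
    trauma_total: int


@dataclass(frozen=True)
class Violation:
    """One record-validation failure: which field, which rule, and why."""

    field: str
    rule: str
    message: str


def _parse_instrument(inst_id: str, raw: dict) -> InstrumentDef:
    items = tuple(
        ItemDef(
            text=str(it["text"]),
            options=tuple(str(o) for o in it["options"]),
            scores=tuple(int(s) for s in it["scores"]),
        )
        for it in raw["items"]
    )
    return InstrumentDef(
        id=inst_id,
        name=str(raw.get("name", inst_id)),
        items=items,
        placeholder=bool(raw.get("placeholder", False)),
    )


def load_instruments(path: str | Path) -> dict[str, InstrumentDef]:
    """Load instrument definitions from a YAML file.

    The file must map instrument ids (AUDIT, LDQ, TRAUMA, ...) to an item
    list; see the packaged ``data/instruments.yaml`` for the schema.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _build_instruments(raw)


def _build_instruments(raw: dict) -> dict[str, InstrumentDef]:
    if not isinstance(raw, dict) or "instruments" not in raw:
        raise ConfigError("instrument definitions must contain an 'instruments' mapping")
    defs = {iid: _parse_instrument(iid, spec) for iid, spec in raw["instruments"].items()}
    _check_canonical_shapes(defs)
    return defs


def _check_canonical_shapes(defs: dict[str, InstrumentDef]) -> None:
    shapes = {"AUDIT": 10, "LDQ": 10, "TRAUMA": 5}
    for iid, n in shapes.items():
        if iid in defs and defs[iid].n_items != n:
            raise ConfigError(f"{iid} must have {n} items, found {defs[iid].n_items}")
    if "AUDIT" in defs and defs["AUDIT"].max_total() != 40:
        raise ConfigError("AUDIT option scores must span a 0-40 total")
    if "LDQ" in defs and defs["LDQ"].max_total() != 30:
        raise ConfigError("LDQ option scores must span a 0-30 total")


@lru_cache(maxsize=1)
def default_instruments() -> dict[str, InstrumentDef]:
    """The packaged instrument definitions (AUDIT, LDQ, placeholder trauma)."""
    text = resources.files("esbi.data").joinpath("instruments.yaml").read_text(encoding="utf-8")
    return _build_instruments(yaml.safe_load(text))


def _lookup_scores(
    instrument: InstrumentDef, indices: Sequence[int], label: str
) -> list[int]:
    """Map option indices to option scores, validating length and range."""
    if indices is None:
        raise ValidationError(f"{label}: no answers supplied")
    indices = list(indices)
    if len(indices) != instrument.n_items:
        raise ValidationError(
            f"{label}: expected {instrument.n_items} answers, got {len(indices)}"
        )
    out = []
    for i, (idx, item) in enumerate(zip(indices, instrument.items), start=1):
        if not isinstance(idx, (int,)) or isinstance(idx, bool):
            raise ValidationError(f"{label} item {i}: answer must be an option index, got {idx!r}")
        if not 0 <= idx < len(item.options):
            raise ValidationError(
                f"{label} item {i}: option index {idx} out of range 0-{len(item.options) - 1}"
            )
        out.append(item.scores[idx])
    return out


def score_audit(
    audit_items: Sequence[int], definitions: dict[str, InstrumentDef] | None = None
) -> tuple[int, int]:
    """Score the 10-item AUDIT.

    Returns ``(audit_total, audit_c)`` where ``audit_c`` sums items 1-3
    (the consumption subscale used for risk classification).
    """
    defs = definitions or default_instruments()
    scores = _lookup_scores(defs["AUDIT"], audit_items, "AUDIT")
    return sum(scores), sum(scores[:3])


def score_ldq(
    ldq_items: Sequence[int], definitions: dict[str, InstrumentDef] | None = None
) -> int:
    """Score the 10-item Leeds Dependence Questionnaire (0-30)."""
    defs = definitions or default_instruments()
    return sum(_lookup_scores(defs["LDQ"], ldq_items, "LDQ"))


def score_trauma(
    trauma_items: Sequence[int], definitions: dict[str, InstrumentDef] | None = None
) -> int:
    """Score the 5-item trauma-history screen: count of affirmatives (0-5)."""
    defs = definitions or default_instruments()
    return sum(_lookup_scores(defs["TRAUMA"], trauma_items, "TRAUMA"))


def score_record(
    record: ResponseRecord, definitions: dict[str, InstrumentDef] | None = None
) -> InstrumentScores:
    """Score all instruments for a gated-in (drinker) record."""
    if not record.drank_past_12m:
        raise ValidationError(
            f"record {record.participant_id}: gated out (no alcohol in past 12 months); "
            "no instrument scores exist"
        )
    total, audit_c = score_audit(record.audit_items, definitions)
    return InstrumentScores(
        audit_total=total,
        audit_c=audit_c,
        ldq_total=score_ldq(record.ldq_items, definitions),
        trauma_total=score_trauma(record.trauma_items, definitions),
    )


def _check_indices(
    violations: list[Violation],
    field_name: str,
    indices: Sequence[int] | None,
    instrument: InstrumentDef,
) -> None:
    if indices is None:
        violations.append(
            Violation(field_name, "required", f"{field_name} required for drinkers")
        )
        return
    if len(indices) != instrument.n_items:
        violations.append(
            Violation(
                field_name,
                "item_count",
                f"{field_name}: expected {instrument.n_items} answers, got {len(indices)}",
            )
        )
        return
    for i, (idx, item) in enumerate(zip(indices, instrument.items), start=1):
        if isinstance(idx, bool) or not isinstance(idx, int) or not 0 <= idx < len(item.options):
            violations.append(
                Violation(
                    f"{field_name}[{i}]",
                    "option_range",
                    f"{field_name} item {i}: option index {idx!r} out of range "
                    f"0-{len(item.options) - 1}",
                )
            )


def validate_record(
    record: ResponseRecord, definitions: dict[str, InstrumentDef] | None = None
) -> list[Violation]:
    """Check every record invariant; return violations instead of raising.

    An empty list means the record is fully valid.  Checks: adult age,
    known gender, the 12-month gate (no downstream answers when gated out;
    all instruments answered when gated in), option-index ranges, episode
    plausibility, and email syntax when present.
    """
    defs = definitions or default_instruments()
    v: list[Violation] = []

    if record.gender not in GENDERS:
        v.append(Violation("gender", "enum", f"gender must be one of {GENDERS}, got {record.gender!r}"))
    if not isinstance(record.age_years, int) or isinstance(record.age_years, bool):
        v.append(Violation("age_years", "type", "age_years must be an integer"))
    elif record.age_years < MIN_AGE_YEARS:
        v.append(
            Violation(
                "age_years", "adult", f"participants must be {MIN_AGE_YEARS}+, got {record.age_years}"
            )
        )

    if not record.drank_past_12m:
        for name in ("audit_items", "episode", "ldq_items", "trauma_items"):
            if getattr(record, name) is not None:
                v.append(
                    Violation(
                        name,
                        "gate",
                        f"{name} present but participant reported no alcohol in past 12 months",
                    )
                )
    else:
        _check_indices(v, "audit_items", record.audit_items, defs["AUDIT"])
        _check_indices(v, "ldq_items", record.ldq_items, defs["LDQ"])
        _check_indices(v, "trauma_items", record.trauma_items, defs["TRAUMA"])
        ep = record.episode
        if ep is None:
            v.append(Violation("episode", "required", "episode report required for drinkers"))
        else:
            for fname in ("max_drinks", "duration_hours", "weight_kg"):
                val = getattr(ep, fname)
                if not isinstance(val, (int, float)) or not math.isfinite(val):
                    v.append(Violation(f"episode.{fname}", "finite", f"{fname} must be finite"))
            if isinstance(ep.max_drinks, (int, float)) and ep.max_drinks < 0:
                v.append(Violation("episode.max_drinks", "nonnegative", "max_drinks must be >= 0"))
            if isinstance(ep.weight_kg, (int, float)) and ep.weight_kg <= 0:
                v.append(Violation("episode.weight_kg", "positive", "weight_kg must be > 0"))
            if (
                isinstance(ep.max_drinks, (int, float))
                and isinstance(ep.duration_hours, (int, float))
                and ep.max_drinks > 0
                and ep.duration_hours <= 0
            ):
                v.append(
                    Violation(
                        "episode.duration_hours",
                        "positive_when_drinking",
                        "duration_hours must be > 0 when max_drinks > 0",
                    )
                )

    if record.email is not None and not _EMAIL_RE.match(record.email):
        v.append(Violation("email", "syntax", f"email {record.email!r} is not a valid address"))
    return v
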