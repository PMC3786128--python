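"""File formats: response CSV/JSON, flow-event CSV, screening and summary output.

CSV dialect: UTF-8, comma-separated, header row, strings quoted as needed.
Booleans serialize as ``true``/``false``; absent values as empty cells.
JSON documents carry a ``schema_version`` field.  Reading validates option
indices against the instrument definitions and reports the offending row
and column; a completely empty file is an empty list, not an error.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ParseError
from .feasibility import CohortSummary, FlowEventRecord, NONCOMPLETION_REASONS
from .instruments import EpisodeReport, ResponseRecord, default_instruments
from .screening import ScreeningCategory

__all__ = [
    "RESPONSE_COLUMNS",
    "FLOW_COLUMNS",
    "read_responses",
    "write_responses",
    "read_flow_events",
    "write_flow_events",
    "write_screening",
    "write_summary",
]

_AUDIT_COLS = [f"audit_{i}" for i in range(1, 11)]
_LDQ_COLS = [f"ldq_{i}" for i in range(1, 11)]
_TRAUMA_COLS = [f"trauma_{i}" for i in range(1, 6)]

RESPONSE_COLUMNS = (
    ["participant_id", "gender", "age_years", "postcode", "drank_past_12m"]
    + _AUDIT_COLS
    + ["episode_max_drinks", "episode_duration_hours", "episode_weight_kg"]
    + _LDQ_COLS
    + _TRAUMA_COLS
    + ["email"]
)

FLOW_COLUMNS = [
    "participant_id",
    "approached",
    "consented",
    "eligible",
    "completed_esbi",
    "noncompletion_reason",
    "category",
    "invited_followup",
    "completed_followup",
    "acceptability_feedback_useful",
    "acceptability_appeal",
]

_BOOL = {"true": True, "false": False}


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def _parse_bool(text: str, row: int, column: str) -> bool:
    try:
        return _BOOL[text.strip().lower()]
    except KeyError:
        raise ParseError(f"expected true/false, got {text!r}", row=row, column=column) from None


def _parse_int(text: str, row: int, column: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"expected an integer, got {text!r}", row=row, column=column) from None


def _parse_items(
    cells: dict[str, str], columns: list[str], instrument_id: str, row: int
) -> tuple[int, ...] | None:
    values = [cells.get(c, "") for c in columns]
    if all(v == "" for v in values):
        return None
    items = default_instruments()[instrument_id].items
    out = []
    for col, text, item in zip(columns, values, items):
        if text == "":
            raise ParseError(f"missing {instrument_id} answer", row=row, column=col)
        idx = _parse_int(text, row, col)
        if not 0 <= idx < len(item.options):
            raise ParseError(
                f"option index {idx} out of range 0-{len(item.options) - 1}",
                row=row,
                column=col,
            )
        out.append(idx)
    return tuple(out)


def _response_to_row(rec: ResponseRecord) -> dict[str, str]:
    row = {
        "participant_id": rec.participant_id,
        "gender": rec.gender,
        "age_years": _fmt(rec.age_years),
        "postcode": rec.postcode,
        "drank_past_12m": _fmt(rec.drank_past_12m),
        "email": _fmt(rec.email),
    }
    for cols, items in ((_AUDIT_COLS, rec.audit_items), (_LDQ_COLS, rec.ldq_items), (_TRAUMA_COLS, rec.trauma_items)):
        for c, v in zip(cols, items if items is not None else [None] * len(cols)):
            row[c] = _fmt(v)
    ep = rec.episode
    row["episode_max_drinks"] = _fmt(ep.max_drinks if ep else None)
    row["episode_duration_hours"] = _fmt(ep.duration_hours if ep else None)
    row["episode_weight_kg"] = _fmt(ep.weight_kg if ep else None)
    return row


def _row_to_response(cells: dict[str, str], row: int) -> ResponseRecord:
    pid = cells.get("participant_id", "")
    if pid == "":
        raise ParseError("missing participant_id", row=row, column="participant_id")
    episode = None
    ep_cells = [cells.get(c, "") for c in ("episode_max_drinks", "episode_duration_hours", "episode_weight_kg")]
    if any(v != "" for v in ep_cells):
        try:
            episode = EpisodeReport(*(float(v) for v in ep_cells))
        except ValueError:
            raise ParseError("episode fields must all be numeric", row=row, column="episode_max_drinks") from None
    email = cells.get("email", "") or None
    return ResponseRecord(
        participant_id=pid,
        gender=cells.get("gender", ""),
        age_years=_parse_int(cells.get("age_years", ""), row, "age_years"),
        postcode=cells.get("postcode", ""),
        drank_past_12m=_parse_bool(cells.get("drank_past_12m", ""), row, "drank_past_12m"),
        audit_items=_parse_items(cells, _AUDIT_COLS, "AUDIT", row),
        episode=episode,
        ldq_items=_parse_items(cells, _LDQ_COLS, "LDQ", row),
        trauma_items=_parse_items(cells, _TRAUMA_COLS, "TRAUMA", row),
        email=email,
    )


def write_responses(path: str | Path, records: Iterable[ResponseRecord]) -> None:
    """Write response records as CSV (or nested JSON for a .json path)."""
    path = Path(path)
    records = list(records)
    if path.suffix.lower() == ".json":
        doc = {
            "schema_version": 1,
            "records": [
                {
                    "participant_id": r.participant_id,
                    "gender": r.gender,
                    "age_years": r.age_years,
                    "postcode": r.postcode,
                    "drank_past_12m": r.drank_past_12m,
                    "audit_items": list(r.audit_items) if r.audit_items else None,
                    "episode": (
                        {
                            "max_drinks": r.episode.max_drinks,
                            "duration_hours": r.episode.duration_hours,
                            "weight_kg": r.episode.weight_kg,
                        }
                        if r.episode
                        else None
                    ),
                    "ldq_items": list(r.ldq_items) if r.ldq_items else None,
                    "trauma_items": list(r.trauma_items) if r.trauma_items else None,
                    "email": r.email,
                }
                for r in records
            ],
        }
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
        return
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=RESPONSE_COLUMNS)
        writer.writeheader()
        for rec in records:
            writer.writerow(_response_to_row(rec))


def read_responses(path: str | Path) -> list[ResponseRecord]:
    """Read response records from CSV or nested JSON.

    Malformed rows raise :class:`ParseError` carrying the (1-based, data)
    row number and column name.  An empty file yields an empty list.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        text = path.read_text(encoding="utf-8").strip()
        if not text:
            return []
        doc = json.loads(text)
        out = []
        for i, r in enumerate(doc.get("records", []), start=1):
            ep = r.get("episode")
            out.append(
                ResponseRecord(
                    participant_id=r["participant_id"],
                    gender=r["gender"],
                    age_years=r["age_years"],
                    postcode=r.get("postcode", ""),
                    drank_past_12m=r["drank_past_12m"],
                    audit_items=tuple(r["audit_items"]) if r.get("audit_items") else None,
                    episode=EpisodeReport(ep["max_drinks"], ep["duration_hours"], ep["weight_kg"]) if ep else None,
                    ldq_items=tuple(r["ldq_items"]) if r.get("ldq_items") else None,
                    trauma_items=tuple(r["trauma_items"]) if r.get("trauma_items") else None,
                    email=r.get("email"),
                )
            )
        return out
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        return [_row_to_response(cells, i) for i, cells in enumerate(reader, start=1)]


def write_flow_events(path: str | Path, records: Iterable[FlowEventRecord]) -> None:
    """Write flow-event records as CSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=FLOW_COLUMNS)
        writer.writeheader()
        for r in records:
            writer.writerow(
                {
                    "participant_id": r.participant_id,
                    "approached": _fmt(r.approached),
                    "consented": _fmt(r.consented),
                    "eligible": _fmt(r.eligible),
                    "completed_esbi": _fmt(r.completed_esbi),
                    "noncompletion_reason": r.noncompletion_reason,
                    "category": r.category.value if r.category else "",
                    "invited_followup": _fmt(r.invited_followup),
                    "completed_followup": _fmt(r.completed_followup),
                    "acceptability_feedback_useful": _fmt(r.acceptability.get("feedback_useful")),
                    "acceptability_appeal": _fmt(r.acceptability.get("appeal")),
                }
            )


def read_flow_events(path: str | Path) -> list[FlowEventRecord]:
    """Read flow-event records from CSV; empty file yields an empty list."""
    out: list[FlowEventRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        for i, cells in enumerate(reader, start=1):
            cat_text = cells.get("category", "")
            if cat_text:
                try:
                    category = ScreeningCategory(cat_text)
                except ValueError:
                    raise ParseError(
                        f"unknown category {cat_text!r}", row=i, column="category"
                    ) from None
            else:
                category = None
            reason = cells.get("noncompletion_reason", "") or "none"
            if reason not in NONCOMPLETION_REASONS:
                raise ParseError(
                    f"unknown noncompletion reason {reason!r}", row=i, column="noncompletion_reason"
                )
            # missing answers are absent keys, not explicit None entries
            acceptability = {}
            for qid, col in (
                ("feedback_useful", "acceptability_feedback_useful"),
                ("appeal", "acceptability_appeal"),
            ):
                text = cells.get(col, "")
                if text != "":
                    acceptability[qid] = _parse_int(text, i, col)
            out.append(
                FlowEventRecord(
                    participant_id=cells.get("participant_id", f"row{i}"),
                    approached=_parse_bool(cells.get("approached", "true"), i, "approached"),
                    consented=_parse_bool(cells.get("consented", "false"), i, "consented"),
                    eligible=_parse_bool(cells.get("eligible", "true"), i, "eligible"),
                    completed_esbi=_parse_bool(cells.get("completed_esbi", "false"), i, "completed_esbi"),
                    noncompletion_reason=reason,
                    category=category,
                    invited_followup=_parse_bool(cells.get("invited_followup", "false"), i, "invited_followup"),
                    completed_followup=_parse_bool(cells.get("completed_followup", "false"), i, "completed_followup"),
                    acceptability=acceptability,
                )
            )
    return out


def write_screening(path: str | Path, results) -> None:
    """Write a batch-screening table (participant_id, audit_c, category, trial_eligible)."""
    results.to_csv(path, index=False)


def write_summary(path: str | Path, summary: CohortSummary | dict) -> None:
    """Write a cohort summary as JSON."""
    doc = summary.as_dict() if isinstance(summary, CohortSummary) else summary
    doc = {"schema_version": 1, **doc}
    Path(path).write_text(json.dumps(doc, indent=1, default=str), encoding="utf-8")
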