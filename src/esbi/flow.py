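"""Survey flow: page sequencing, the 12-month gate, and interrupt/resume.

The program is a fixed page sequence::

    intro -> demographics -> gate12m -> audit -> episode -> ldq -> trauma
          -> feedback -> thanks

with one branch: answering "no" at the 12-month gate jumps straight to the
thank-you page and completes the session.  Participants interrupted (e.g.
called for their appointment) are resumed later via an opaque linkage
identifier; resume restores the session at exactly the page it was
interrupted on, with all prior answers intact.  Visited pages can never be
re-answered.
"""

from __future__ import annotations

import json
import secrets
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Protocol

from .errors import SequencingError, SessionNotFoundError, StateError, ValidationError
from .feedback import FeedbackBundle, FeedbackConfig, build_feedback, default_feedback_config
from .instruments import (
    EpisodeReport,
    GENDERS,
    MIN_AGE_YEARS,
    ResponseRecord,
    _EMAIL_RE,
    default_instruments,
    score_record,
)
from .screening import ScreeningResult, classify, screen_record

__all__ = [
    "PAGES",
    "FlowSession",
    "new_linkage_id",
    "start_session",
    "advance",
    "interrupt",
    "resume",
    "finalize",
    "SessionStore",
    "MemorySessionStore",
    "JsonFileSessionStore",
]

PAGES = (
    "intro",
    "demographics",
    "gate12m",
    "audit",
    "episode",
    "ldq",
    "trauma",
    "feedback",
    "thanks",
)

IN_PROGRESS = "in_progress"
INTERRUPTED = "interrupted"
COMPLETED = "completed"


@dataclass
class FlowSession:
    """One participant's progress through the page sequence."""

    linkage_id: str
    current_page: str = "intro"
    answers: dict[str, Any] = field(default_factory=dict)
    status: str = IN_PROGRESS

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "linkage_id": self.linkage_id,
            "current_page": self.current_page,
            "answers": self.answers,
            "status": self.status,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FlowSession":
        return cls(
            linkage_id=d["linkage_id"],
            current_page=d["current_page"],
            answers=dict(d["answers"]),
            status=d["status"],
        )


def new_linkage_id() -> str:
    """A fresh URL-safe random linkage identifier."""
    return secrets.token_urlsafe(12)


def start_session(linkage_id: str | None = None) -> FlowSession:
    """Begin a new session on the intro page."""
    return FlowSession(linkage_id=linkage_id or new_linkage_id())


def _validate_page_answers(session: FlowSession, page: str, answers: dict) -> dict:
    """Validate answers for one page; raise without touching the session."""
    defs = default_instruments()
    if page == "intro":
        return {}
    if page == "demographics":
        gender = answers.get("gender")
        age = answers.get("age_years")
        postcode = answers.get("postcode", "")
        if gender not in GENDERS:
            raise ValidationError(f"gender must be one of {GENDERS}, got {gender!r}")
        if isinstance(age, bool) or not isinstance(age, int) or age < MIN_AGE_YEARS:
            raise ValidationError(f"age_years must be an integer >= {MIN_AGE_YEARS}, got {age!r}")
        return {"gender": gender, "age_years": age, "postcode": str(postcode)}
    if page == "gate12m":
        drank = answers.get("drank_past_12m")
        if not isinstance(drank, bool):
            raise ValidationError("drank_past_12m must be a boolean")
        return {"drank_past_12m": drank}
    if page in ("audit", "ldq", "trauma"):
        inst = defs[page.upper()]
        items = answers.get(f"{page}_items")
        if items is None or len(items) != inst.n_items:
            raise ValidationError(f"{page} page requires {inst.n_items} answers")
        for i, (idx, item) in enumerate(zip(items, inst.items), start=1):
            if isinstance(idx, bool) or not isinstance(idx, int) or not 0 <= idx < len(item.options):
                raise ValidationError(f"{page} item {i}: option index {idx!r} out of range")
        return {f"{page}_items": list(items)}
    if page == "episode":
        try:
            drinks = float(answers["max_drinks"])
            hours = float(answers["duration_hours"])
            weight = float(answers["weight_kg"])
        except (KeyError, TypeError, ValueError):
            raise ValidationError(
                "episode page requires numeric max_drinks, duration_hours, weight_kg"
            ) from None
        if drinks < 0:
            raise ValidationError("max_drinks must be >= 0")
        if weight <= 0:
            raise ValidationError("weight_kg must be > 0")
        if drinks > 0 and hours <= 0:
            raise ValidationError("duration_hours must be > 0 when max_drinks > 0")
        return {"max_drinks": drinks, "duration_hours": hours, "weight_kg": weight}
    if page == "feedback":
        email = answers.get("email")
        if email is not None and not _EMAIL_RE.match(str(email)):
            raise ValidationError(f"email {email!r} is not a valid address")
        return {"email": email}
    raise SequencingError(f"page {page!r} accepts no answers")


def advance(session: FlowSession, page_answers: dict | None = None, page: str | None = None) -> FlowSession:
    """Record the current page's answers and move to the next page.

    ``page``, when given, must match the session's current page (guards
    against answers meant for a different page).  The gate answered "no"
    jumps to the thank-you page and completes the session; after the
    feedback page the session completes likewise.  On validation failure the
    session is unchanged.
    """
    if session.status == COMPLETED:
        raise SequencingError("session already completed")
    if session.status == INTERRUPTED:
        raise StateError("session is interrupted; resume it before advancing")
    current = session.current_page
    if page is not None and page != current:
        raise SequencingError(f"answers supplied for page {page!r} but session is on {current!r}")
    validated = _validate_page_answers(session, current, page_answers or {})

    session.answers.update(validated)
    if current == "gate12m" and validated["drank_past_12m"] is False:
        session.current_page = "thanks"
        session.status = COMPLETED
        return session
    nxt = PAGES[PAGES.index(current) + 1]
    session.current_page = nxt
    if nxt == "thanks":
        session.status = COMPLETED
    return session


def interrupt(session: FlowSession) -> FlowSession:
    """Mark an in-progress session interrupted (e.g. called for appointment)."""
    if session.status == COMPLETED:
        raise StateError("completed sessions cannot be interrupted")
    session.status = INTERRUPTED
    return session


class SessionStore(Protocol):
    """Pluggable persistence keyed by linkage identifier."""

    def save(self, session: FlowSession) -> None: ...

    def load(self, linkage_id: str) -> FlowSession: ...


class MemorySessionStore:
    """Dict-backed store for tests and single-process use."""

    def __init__(self) -> None:
        self._sessions: dict[str, dict] = {}

    def save(self, session: FlowSession) -> None:
        self._sessions[session.linkage_id] = session.to_dict()

    def load(self, linkage_id: str) -> FlowSession:
        try:
            return FlowSession.from_dict(self._sessions[linkage_id])
        except KeyError:
            raise SessionNotFoundError(f"no session for linkage id {linkage_id!r}") from None


class JsonFileSessionStore:
    """Single-file JSON store: one object per linkage id under 'sessions'."""

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)

    def _read_all(self) -> dict:
        if not self.path.exists():
            return {"schema_version": 1, "sessions": {}}
        with open(self.path, "r", encoding="utf-8") as fh:
            return json.load(fh)

    def save(self, session: FlowSession) -> None:
        data = self._read_all()
        data["sessions"][session.linkage_id] = session.to_dict()
        with open(self.path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    def load(self, linkage_id: str) -> FlowSession:
        data = self._read_all()
        try:
            return FlowSession.from_dict(data["sessions"][linkage_id])
        except KeyError:
            raise SessionNotFoundError(f"no session for linkage id {linkage_id!r}") from None


def resume(store: SessionStore, linkage_id: str) -> FlowSession:
    """Restore a persisted session at exactly its interrupted page.

    A completed session comes back completed — no pages are re-asked.
    """
    session = store.load(linkage_id)
    if session.status == INTERRUPTED:
        session.status = IN_PROGRESS
    return session


def record_from_session(session: FlowSession) -> ResponseRecord:
    """Assemble the item-level response record from a completed session."""
    a = session.answers
    episode = None
    if "max_drinks" in a:
        episode = EpisodeReport(a["max_drinks"], a["duration_hours"], a["weight_kg"])
    return ResponseRecord(
        participant_id=session.linkage_id,
        gender=a["gender"],
        age_years=a["age_years"],
        postcode=a.get("postcode", ""),
        drank_past_12m=a["drank_past_12m"],
        audit_items=tuple(a["audit_items"]) if "audit_items" in a else None,
        episode=episode,
        ldq_items=tuple(a["ldq_items"]) if "ldq_items" in a else None,
        trauma_items=tuple(a["trauma_items"]) if "trauma_items" in a else None,
        email=a.get("email"),
    )


def finalize(
    session: FlowSession, config: FeedbackConfig | None = None
) -> tuple[ResponseRecord, ScreeningResult, FeedbackBundle | None]:
    """Turn a completed session into (record, screening result, feedback).

    Gated-out nondrinkers yield no feedback bundle; drinkers yield all six
    feedback components.
    """
    if session.status != COMPLETED:
        raise StateError(f"cannot finalize a session in state {session.status!r}")
    record = record_from_session(session)
    if not record.drank_past_12m:
        return record, classify(False), None
    result = screen_record(record)
    bundle = build_feedback(record, result.scores, config or default_feedback_config())
    return record, result, bundle
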