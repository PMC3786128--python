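"""Personalized drinking feedback: the six components and their suppression.

Every participant who passes the 12-month gate receives:

1. AUDIT total with a risk-band message;
2. an estimated peak blood alcohol concentration (BAC) for the heaviest
   recent drinking occasion, with a tier of behavioural/physiological
   consequences;
3. an estimated monthly spend on alcohol;
4. a bar-chart comparison of typical episodic consumption against the
   guideline single-occasion limit and the same-age/gender population norm;
5. the same comparison for weekly consumption against the weekly guideline
   (daily limit x 7) and the weekly norm;
6. the LDQ score with a dependence-risk message.

Normative feedback (components 4 and 5) is *suppressed* whenever the
participant's own consumption is strictly below the guideline limit, to
avoid the risk of people "drinking up" to the norm.  Suppression is decided
independently for the episodic and weekly comparisons.

Peak BAC uses the Widmark body-water model with time-based elimination::

    BAC = (drinks x grams_per_drink) / (weight_kg x r x 10) - beta x hours

in g/100 mL, clamped at zero; ``r`` is the gender-specific distribution
ratio and ``beta`` the elimination rate.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigError, ValidationError
from .instruments import EpisodeReport, InstrumentScores, ResponseRecord

__all__ = [
    "AGE_GROUPS",
    "age_group",
    "GuidelineConfig",
    "BacParams",
    "NormCell",
    "Band",
    "InfoPage",
    "FeedbackConfig",
    "Comparison",
    "FeedbackBundle",
    "load_feedback_config",
    "default_feedback_config",
    "estimate_peak_bac",
    "estimate_monthly_spend",
    "compare_to_guideline_and_norm",
    "audit_band",
    "ldq_band",
    "build_feedback",
    "render_feedback",
]

AGE_GROUPS = ("18-34", "35-54", "55+")

WEEKS_PER_MONTH = 52 / 12  # ~4.33, used to convert monthly to weekly consumption


def age_group(age_years: int) -> str:
    """Bucket an adult age into the norm-table age groups."""
    if age_years < 18:
        raise ValidationError(f"age {age_years} below adult minimum")
    if age_years <= 34:
        return "18-34"
    if age_years <= 54:
        return "35-54"
    return "55+"


@dataclass(frozen=True)
class GuidelineConfig:
    """Medical drinking-guideline limits, in Australian standard drinks."""

    single_occasion_limit: float = 4.0
    daily_limit: float = 2.0
    standard_drink_grams: float = 10.0

    def __post_init__(self) -> None:
        if min(self.single_occasion_limit, self.daily_limit, self.standard_drink_grams) <= 0:
            raise ConfigError("guideline limits and standard drink size must be positive")

    @property
    def weekly_limit(self) -> float:
        return self.daily_limit * 7


@dataclass(frozen=True)
class BacParams:
    """Widmark constants: gender-specific distribution ratio and elimination."""

    distribution_ratio: dict[str, float] = field(
        default_factory=lambda: {"male": 0.68, "female": 0.55}
    )
    elimination_rate_per_hour: float = 0.015  # g/100 mL per hour

    def __post_init__(self) -> None:
        for g, r in self.distribution_ratio.items():
            if not 0 < r <= 1:
                raise ConfigError(f"distribution ratio for {g} must be in (0, 1], got {r}")
        if self.elimination_rate_per_hour <= 0:
            raise ConfigError("elimination rate must be positive")


@dataclass(frozen=True)
class NormCell:
    typical_occasion_drinks: float
    weekly_drinks: float


@dataclass(frozen=True)
class Band:
    """A contiguous score band with a label and a message."""

    lo: int
    hi: int
    label: str
    message: str


@dataclass(frozen=True)
class InfoPage:
    title: str
    body: str


def _check_bands(bands: tuple[Band, ...], lo: int, hi: int, name: str) -> None:
    """Bands must partition [lo, hi] with no gaps or overlaps."""
    expect = lo
    for b in bands:
        if b.lo != expect or b.hi < b.lo:
            raise ConfigError(f"{name} bands do not partition {lo}-{hi} (at {b.lo}-{b.hi})")
        expect = b.hi + 1
    if expect != hi + 1:
        raise ConfigError(f"{name} bands stop at {expect - 1}, expected {hi}")


@dataclass(frozen=True)
class FeedbackConfig:
    """Everything the feedback computation needs, loadable from YAML."""

    guidelines: GuidelineConfig
    bac: BacParams
    norms: dict[tuple[str, str], NormCell]  # keyed by (gender, age_group)
    audit_bands: tuple[Band, ...]
    ldq_bands: tuple[Band, ...]
    bac_tiers: tuple[tuple[float, str], ...]  # (lower threshold, text), ascending
    frequency_days_per_month: tuple[float, ...]
    typical_drinks_midpoint: tuple[float, ...]
    price_per_drink: float
    currency: str
    info_pages: tuple[InfoPage, ...]

    def __post_init__(self) -> None:
        _check_bands(self.audit_bands, 0, 40, "AUDIT")
        _check_bands(self.ldq_bands, 0, 30, "LDQ")
        if self.price_per_drink <= 0:
            raise ConfigError("price_per_drink must be positive")
        if self.frequency_days_per_month[0] != 0:
            raise ConfigError("frequency midpoint for 'never' must be 0")
        if list(t for t, _ in self.bac_tiers) != sorted(t for t, _ in self.bac_tiers):
            raise ConfigError("bac tier thresholds must be ascending")

    def norm_cell(self, gender: str, group: str) -> NormCell:
        try:
            return self.norms[(gender, group)]
        except KeyError:
            raise ConfigError(f"no norm-table cell for ({gender}, {group})") from None


def _config_from_raw(raw: dict) -> FeedbackConfig:
    norms = {
        (g, grp): NormCell(float(cell["typical_occasion_drinks"]), float(cell["weekly_drinks"]))
        for g, groups in raw["norms"].items()
        for grp, cell in groups.items()
    }
    return FeedbackConfig(
        guidelines=GuidelineConfig(**{k: float(v) for k, v in raw["guidelines"].items()}),
        bac=BacParams(
            distribution_ratio={g: float(r) for g, r in raw["bac"]["distribution_ratio"].items()},
            elimination_rate_per_hour=float(raw["bac"]["elimination_rate_per_hour"]),
        ),
        norms=norms,
        audit_bands=tuple(Band(int(b["lo"]), int(b["hi"]), b["label"], b["message"]) for b in raw["audit_bands"]),
        ldq_bands=tuple(Band(int(b["lo"]), int(b["hi"]), b["label"], b["message"]) for b in raw["ldq_bands"]),
        bac_tiers=tuple((float(t["threshold"]), str(t["text"])) for t in raw["bac_tiers"]),
        frequency_days_per_month=tuple(float(x) for x in raw["frequency_days_per_month"]),
        typical_drinks_midpoint=tuple(float(x) for x in raw["typical_drinks_midpoint"]),
        price_per_drink=float(raw["price_per_drink"]),
        currency=str(raw.get("currency", "AUD")),
        info_pages=tuple(InfoPage(str(p["title"]), str(p["body"])) for p in raw["info_pages"]),
    )


def load_feedback_config(path: str | Path) -> FeedbackConfig:
    """Load a feedback configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return _config_from_raw(yaml.safe_load(fh))


@lru_cache(maxsize=1)
def default_feedback_config() -> FeedbackConfig:
    """The packaged defaults (placeholder messages and norms)."""
    text = resources.files("esbi.data").joinpath("feedback_defaults.yaml").read_text("utf-8")
    return _config_from_raw(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# component computations


def estimate_peak_bac(
    episode: EpisodeReport,
    gender: str,
    bac: BacParams | None = None,
    standard_drink_grams: float = 10.0,
) -> float:
    """Widmark peak BAC estimate in g/100 mL, clamped at zero.

    Zero drinks always yield 0.0 regardless of duration or weight.
    """
    bac = bac or BacParams()
    if episode.max_drinks == 0:
        return 0.0
    if episode.max_drinks < 0:
        raise ValidationError(f"max_drinks must be >= 0, got {episode.max_drinks}")
    if episode.weight_kg <= 0:
        raise ValidationError(f"weight_kg must be > 0, got {episode.weight_kg}")
    if episode.duration_hours <= 0:
        raise ValidationError(
            f"duration_hours must be > 0 when drinking, got {episode.duration_hours}"
        )
    try:
        r = bac.distribution_ratio[gender]
    except KeyError:
        raise ValidationError(f"no distribution ratio configured for gender {gender!r}") from None
    grams = episode.max_drinks * standard_drink_grams
    peak = grams / (episode.weight_kg * r * 10.0) - bac.elimination_rate_per_hour * episode.duration_hours
    return max(peak, 0.0)


def estimate_monthly_spend(
    frequency_idx: int,
    typical_drinks_idx: int,
    price_per_drink: float,
    config: FeedbackConfig | None = None,
) -> float:
    """Monthly alcohol spend from AUDIT items 1-2 band midpoints.

    spend = drinking-days-per-month midpoint x typical-drinks midpoint x price.
    Frequency "never" (index 0) always yields 0.
    """
    cfg = config or default_feedback_config()
    if price_per_drink <= 0:
        raise ConfigError(f"price_per_drink must be positive, got {price_per_drink}")
    try:
        days = cfg.frequency_days_per_month[frequency_idx]
        drinks = cfg.typical_drinks_midpoint[typical_drinks_idx]
    except (IndexError, TypeError):
        raise ConfigError(
            f"no midpoint configured for frequency index {frequency_idx!r} "
            f"/ typical-drinks index {typical_drinks_idx!r}"
        ) from None
    return days * drinks * price_per_drink


@dataclass(frozen=True)
class Comparison:
    """One bar-chart comparison: own vs guideline vs norm, shown or suppressed."""

    own: float
    guideline: float
    norm: float
    status: str  # "shown" | "suppressed"


def compare_to_guideline_and_norm(own: float, guideline_limit: float, norm: float) -> Comparison:
    """Build a comparison, withholding the norm bars for below-guideline drinkers.

    Suppressed iff own consumption is strictly lower than the guideline
    limit; at or above the limit all three bars are shown.
    """
    if min(own, guideline_limit, norm) < 0:
        raise ValidationError("comparison inputs must be non-negative")
    status = "suppressed" if own < guideline_limit else "shown"
    return Comparison(own=own, guideline=guideline_limit, norm=norm, status=status)


def _find_band(bands: tuple[Band, ...], score: int, name: str) -> Band:
    for b in bands:
        if b.lo <= score <= b.hi:
            return b
    raise ValidationError(f"{name} score {score} outside banded range")


def audit_band(audit_total: int, config: FeedbackConfig | None = None) -> Band:
    """Risk band for a full-AUDIT total (default zones 0-7/8-15/16-19/20-40)."""
    cfg = config or default_feedback_config()
    return _find_band(cfg.audit_bands, audit_total, "AUDIT")


def ldq_band(ldq_total: int, config: FeedbackConfig | None = None) -> Band:
    """Dependence-risk band for an LDQ total (default 0/1-10/11-20/21-30)."""
    cfg = config or default_feedback_config()
    return _find_band(cfg.ldq_bands, ldq_total, "LDQ")


def bac_tier_text(peak_bac: float, config: FeedbackConfig | None = None) -> str:
    """Consequence text for the highest tier at or below the estimated BAC."""
    cfg = config or default_feedback_config()
    text = cfg.bac_tiers[0][1]
    for threshold, t in cfg.bac_tiers:
        if peak_bac >= threshold:
            text = t
    return text


@dataclass(frozen=True)
class FeedbackBundle:
    """All six computed feedback components for one participant."""

    participant_id: str
    audit_score: int
    audit_band: Band
    peak_bac: float
    bac_text: str
    monthly_spend: float
    currency: str
    episodic_comparison: Comparison
    weekly_comparison: Comparison
    ldq_score: int
    ldq_band: Band


def build_feedback(
    record: ResponseRecord,
    scores: InstrumentScores,
    config: FeedbackConfig | None = None,
) -> FeedbackBundle:
    """Compute the full six-component bundle for a gated-in participant.

    Typical episodic consumption is the AUDIT item 2 band midpoint; weekly
    consumption is the item 1 days-per-month midpoint times that, converted
    to a week.  Suppression applies independently to each comparison.
    """
    cfg = config or default_feedback_config()
    if not record.drank_past_12m:
        raise ValidationError("feedback is only built for participants who drank in the past 12 months")
    if record.audit_items is None or record.episode is None:
        raise ValidationError("record must carry AUDIT answers and an episode report")

    freq_idx, typical_idx = record.audit_items[0], record.audit_items[1]
    typical_drinks = cfg.typical_drinks_midpoint[typical_idx]
    days_per_month = cfg.frequency_days_per_month[freq_idx]
    # a participant who answered "never" to item 1 drinks 0/week by construction
    own_weekly = days_per_month * typical_drinks / WEEKS_PER_MONTH
    own_episodic = typical_drinks if days_per_month > 0 else 0.0

    cell = cfg.norm_cell(record.gender, age_group(record.age_years))
    gl = cfg.guidelines
    peak = estimate_peak_bac(record.episode, record.gender, cfg.bac, gl.standard_drink_grams)
    return FeedbackBundle(
        participant_id=record.participant_id,
        audit_score=scores.audit_total,
        audit_band=audit_band(scores.audit_total, cfg),
        peak_bac=peak,
        bac_text=bac_tier_text(peak, cfg),
        monthly_spend=estimate_monthly_spend(freq_idx, typical_idx, cfg.price_per_drink, cfg),
        currency=cfg.currency,
        episodic_comparison=compare_to_guideline_and_norm(
            own_episodic, gl.single_occasion_limit, cell.typical_occasion_drinks
        ),
        weekly_comparison=compare_to_guideline_and_norm(
            own_weekly, gl.weekly_limit, cell.weekly_drinks
        ),
        ldq_score=scores.ldq_total,
        ldq_band=ldq_band(scores.ldq_total, cfg),
    )


# ---------------------------------------------------------------------------
# rendering


def _comparison_lines(name: str, cmp: Comparison) -> list[str]:
    lines = [f"{name} consumption: {cmp.own:.1f} standard drinks"]
    lines.append(f"  Guideline limit: {cmp.guideline:.1f} standard drinks")
    if cmp.status == "shown":
        lines.append(f"  Average for people your age and gender: {cmp.norm:.1f} standard drinks")
    return lines


def render_feedback(
    bundle: FeedbackBundle,
    format: str = "text",
    config: FeedbackConfig | None = None,
) -> str:
    """Render a bundle as a deterministic UTF-8 text or standalone HTML document.

    Suppressed comparisons omit the norm bar entirely; the three static
    information pages from the configuration are appended.  Identical inputs
    produce byte-identical output.
    """
    cfg = config or default_feedback_config()
    if format not in ("text", "html"):
        raise ValidationError(f"unknown render format {format!r} (expected 'text' or 'html')")

    sections: list[tuple[str, list[str]]] = [
        (
            "Your AUDIT score",
            [f"Score: {bundle.audit_score} ({bundle.audit_band.label})", bundle.audit_band.message],
        ),
        (
            "Estimated peak blood alcohol concentration",
            [f"Peak BAC: {bundle.peak_bac:.3f} g/100 mL", bundle.bac_text],
        ),
        (
            "Estimated monthly spend on alcohol",
            [f"{bundle.currency} {bundle.monthly_spend:.2f} per month"],
        ),
        ("Your typical occasion", _comparison_lines("Typical occasion", bundle.episodic_comparison)),
        ("Your typical week", _comparison_lines("Weekly", bundle.weekly_comparison)),
        (
            "Alcohol dependence (LDQ)",
            [f"Score: {bundle.ldq_score} ({bundle.ldq_band.label})", bundle.ldq_band.message],
        ),
    ]
    sections += [(page.title, [page.body]) for page in cfg.info_pages]

    if format == "text":
        parts = [f"Personalized feedback for {bundle.participant_id}", "=" * 40]
        for title, lines in sections:
            parts.append("")
            parts.append(title)
            parts.append("-" * len(title))
            parts.extend(lines)
        return "\n".join(parts) + "\n"

    esc = _html.escape
    body = [f"<h1>Personalized feedback for {esc(bundle.participant_id)}</h1>"]
    for title, lines in sections:
        body.append(f"<h2>{esc(title)}</h2>")
        for line in lines:
            body.append(f"<p>{esc(line)}</p>")
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        "<title>Personalized feedback</title></head>\n<body>\n"
        + "\n".join(body)
        + "\n</body></html>\n"
    )
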