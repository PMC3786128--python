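# Methods

## Scope and model of the program

The package models a self-administered e-SBI program as four cooperating
pieces: (1) instruments-as-data with lookup scoring, (2) an AUDIT-C risk
classifier, (3) a six-component personalized-feedback computation with
normative-feedback suppression, and (4) feasibility statistics over
participant-flow events.  A survey-flow automaton ties (1)–(3) together
the way the program is experienced page by page, and a synthetic-cohort
generator supplies inputs for everything.

## Instruments and scoring

Item texts, response options and per-option integer scores are data
(`src/esbi/data/instruments.yaml`), not code.  AUDIT items 1–8 score 0–4,
items 9–10 score 0/2/4; the AUDIT-C is the sum of items 1–3.  LDQ items
score 0–3.  The trauma screen is a count of affirmative answers out of 5;
its shipped wording is a **placeholder** (flagged in the file and in
`InstrumentDef.placeholder`) because the engine's source program does not
reproduce the published scale.  Missing or out-of-range answers raise a
validation error naming the item; nothing is imputed or prorated, because
the program is self-administered to completion and no prorating rule
exists for it.

## Classification

Categories partition all inputs: the 12-month gate first, then AUDIT-C
bands <5 / 5–9 / ≥10.  Trial eligibility is exactly the 5–9 band: the
5-point floor trades sensitivity for specificity in identifying hazardous
or harmful drinking, and scores above 9 signal probable dependence needing
more than brief intervention.  Only the AUDIT-C — not full-AUDIT zones —
drives classification, because a trial built on this engine would screen
with the AUDIT-C alone to limit assessment reactivity; full-AUDIT bands
appear only inside the feedback.

## Feedback components

**Peak BAC** uses the Widmark body-water model with linear elimination:
`BAC = (drinks × grams_per_drink) / (weight_kg × r × 10) − β × hours`,
in g/100 mL, clamped at zero; defaults r = 0.68 (male) / 0.55 (female),
β = 0.015 g/100 mL/h, 10 g per Australian standard drink.  These are
standard forensic conventions; they are configuration (`BacParams`), not
constants, precisely because they are conventions.  Zero reported drinks
short-circuit to 0.0 regardless of the other fields.

**Monthly spend** maps AUDIT item 1 (drinking frequency) and item 2
(typical drinks per drinking day) to documented numeric midpoints —
days/month {0, 0.5, 3, 10.8, 22} and drinks {1.5, 3.5, 5.5, 8, 10} — and
multiplies by a configurable price per standard drink (default AUD 5).
"Never" yields exactly zero; spend is linear in price by construction.

**Comparisons.** Typical episodic consumption is the item 2 midpoint (the
heaviest-episode report feeds only the BAC, since a single worst occasion
is not "typical" consumption); weekly consumption is the days-per-month
midpoint × typical drinks ÷ (52/12) weeks.  Guideline limits default to
the 2009 Australian values: 4 drinks per occasion, 2 per day (weekly limit
2 × 7 = 14).  The norm table is keyed by gender × age group (18–34 /
35–54 / 55+); the shipped values are labelled placeholders.  The
**suppression rule** is strict: the norm bars are withheld iff own
consumption is strictly below the guideline limit (own = guideline shows
them), applied independently to the episodic and weekly comparisons, so a
below-guideline drinker is never shown a higher "average" to drink up to.

**Bands.** AUDIT bands default to the WHO zones 0–7 / 8–15 / 16–19 /
20–40; LDQ bands to 0 / 1–10 / 11–20 / 21–30 (the source program cites no
cut points, so these are package defaults, config-overridable).  Band
tables are validated to partition their domains with no gaps or overlaps.

Rendering is deterministic (byte-identical for identical inputs) to text
or standalone HTML; suppressed comparisons omit the norm line entirely,
and the three static information pages from the configuration are
appended.  All shipped message and page texts are placeholders — the
original program's wording is not public and is not imitated.

## Survey flow

The page order is a fixed automaton; the only branch is the 12-month gate
jumping to the thank-you page (such sessions complete with no instrument
answers).  Sessions are keyed by caller-supplied opaque linkage ids (a
URL-safe random generator is provided); persistence is a pluggable store
with in-memory and single-JSON-file implementations.  Resume restores the
session at exactly its interrupted page; visited pages can never be
re-answered — with no revision rule to follow, forbidding silent
post-hoc edits is the conservative choice for data integrity.  Email
addresses are syntactically validated at entry, since hand-written
addresses are a known source of lost follow-up contact.

## Feasibility statistics

Flow-event records carry three booleans (approached / consented /
eligible, where eligible means "not determined ineligible"), completion
with a reason (technical vs called away), the screening category,
follow-up invitation/completion, and per-question acceptability answers.
Invariants (consent implies approach, completion implies eligible consent,
follow-up implies invitation, reasons partition noncompleters) are checked
before any summary; violating records are listed by id.

Percentages are `100 × count / denominator` rounded **half-up**: one
decimal for participant-flow percentages, integers for acceptability,
noncompletion-reason and retention percentages — the precisions such
tables are printed at.  Zero-denominator ratios are reported as undefined
(`pct: None`), never 0% or 100%.  Acceptability column percentages use the
category's completer count as denominator, so missing answers leave a
column summing below 100% rather than silently shrinking the base.
Quartiles use linear interpolation between order statistics (numpy's
default), stated explicitly because published tables rarely name their
convention.

The deterministic `paper_flow_fixture()` encodes one published
recruitment episode — 172 approached = 108 consented + 62 refused + 2
ineligible; 2 post-consent exclusions; 7 noncompleters (3 technical, 4
called away); 99 completers split 15/43/33/8; 69 invited to follow-up, 52
completing (30/22 in the hazardous-harmful subgroup) — together with the
published "feedback useful" and "appeal" acceptability columns, each of
which has one missing answer in the hazardous-harmful column (the
published column sums to 32 of n=33).  One published follow-up table row
("I would recommend…") is internally inconsistent in its source and is
excluded.

## Synthetic cohorts

The generator emulates a recruitment episode at the observed study
conditions, which are its defaults: consent 108/172, pre-/post-consent
ineligibility 2/172 and 2/108, completion 99/106 with a 3:4
technical/called split, completer categories 15/43/33/8, follow-up
invitation 32/43, 30/33, 7/8 and completion 26/32, 22/30, 4/7 by drinker
category.  Each drinker's AUDIT items 1–3 are drawn uniformly from the
enumerated set of score triples whose sum lies in the target category's
AUDIT-C range — this makes the intended category round-trip through
scoring and classification with probability 1, a property the tests
assert at 100%.  AUDIT items 4–10, LDQ, trauma and episode magnitudes are
drawn from category-conditioned distributions chosen to couple
monotonically with severity and to land near the observed per-category
medians; they are synthetic choices, not empirical estimates, and real
covariance between scales is not emulated beyond that monotone coupling.
A single seeded generator stream makes cohorts byte-reproducible.

Passing tests on synthetic cohorts therefore demonstrate the engine's
arithmetic, invariants and round-trips — not that real outpatients answer
this way.

## Problem sizes and numerical notes

Tests run the generator at n = 120–400 approached; the mixture-recovery
check uses n = 10,000 with a 3-standard-error binomial band; the
acceptance script uses the 172-record fixture plus a 2,000-participant
synthetic cohort.  All scoring is integer arithmetic; the only
floating-point computations (BAC, spend, weekly consumption) are single
closed-form expressions with no conditioning concerns.  Half-up rounding
goes through `decimal` to avoid binary-float ties.

## Known limitations

* Trauma-scale wording, norm values, and all feedback prose are
  placeholders; deployments must supply their own configuration.
* Acceptability questions are modelled as single-choice with optional
  missingness; free-text feedback is out of scope.
* The flow engine is single-process; the store interface is pluggable but
  no concurrent-access semantics are defined.
* Follow-up questionnaire content is carried as opaque answers; only
  completion is summarized.
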