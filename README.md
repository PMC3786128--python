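# esbi

An engine for **electronic alcohol screening and brief intervention
(e-SBI)** in health-care waiting rooms: a self-administered questionnaire
(AUDIT, a heaviest-episode report, LDQ, a trauma screen) followed by
computer-generated personalized feedback on drinking, plus the feasibility
statistics used to evaluate a recruitment episode of such a program.  It is
written for researchers piloting or trialling e-SBI in hospital outpatient
or similar settings, and for anyone who needs reproducible AUDIT/AUDIT-C
scoring and risk classification.

## What it computes

**Screening.** The AUDIT (10 items, total 0–40) is scored by per-item
option lookup; the AUDIT-C consumption subscale is the sum of items 1–3
(0–12).  Participants are classified:

| category | rule | eligible for a brief-intervention trial |
|---|---|---|
| `nondrinker_12m` | no alcohol in past 12 months | no |
| `negative` | AUDIT-C < 5 | no |
| `hazardous_harmful` | 5 ≤ AUDIT-C ≤ 9 | **yes** |
| `possible_dependence` | AUDIT-C ≥ 10 | no |

**Feedback.** Six components per drinker: AUDIT band with message; peak
blood alcohol concentration for the heaviest recent occasion via the
Widmark model, BAC = A/(W·r·10) − β·t in g/100 mL (A grams ethanol, W body
weight in kg, r the gender-specific distribution ratio, β the elimination
rate, t hours), clamped at 0; estimated monthly spend; bar-chart
comparisons of episodic and weekly consumption against guideline limits
and age/gender norms — with the norm bars *suppressed* whenever own
consumption is below the guideline, so nobody "drinks up" to the average;
and the LDQ dependence band.

**Survey flow.** A fixed page automaton (intro → demographics → 12-month
gate → AUDIT → episode → LDQ → trauma → feedback → thanks) with a gate
branch straight to thanks, plus interrupt/resume keyed by an opaque
linkage identifier, so participants called away mid-survey continue where
they stopped.

**Feasibility.** From participant-flow event records: consent, refusal and
eligibility rates, the screening mix, completion with reasons, follow-up
retention (overall and by subgroup), acceptability crosstabs, and medians
with 25th/75th percentiles — all percentages recomputable from their own
counts under a declared half-up rounding rule.

**Synthetic cohorts.** A seeded generator produces item-level respondents
with a requested category mixture (AUDIT items 1–3 are drawn uniformly
from the exact solution set of score triples for the target AUDIT-C range,
so the intended category always round-trips through scoring), plus flow
records for a whole recruitment episode.

## Worked example

```python
from esbi import (ResponseRecord, EpisodeReport, screen_record,
                  build_feedback, render_feedback)

rec = ResponseRecord(
    participant_id="demo-01", gender="male", age_years=42, postcode="2300",
    drank_past_12m=True,
    audit_items=(3, 2, 2, 1, 0, 0, 1, 0, 0, 2),
    episode=EpisodeReport(max_drinks=10.0, duration_hours=4.0, weight_kg=80.0),
    ldq_items=(0, 1, 2, 3, 0, 1, 2, 3, 1, 2),
    trauma_items=(1, 0, 1, 0, 0),
)
res = screen_record(rec)
print("category:", res.category.value, "| trial eligible:", res.trial_eligible)
print("AUDIT", res.scores.audit_total, "AUDIT-C", res.scores.audit_c,
      "LDQ", res.scores.ldq_total)
print(render_feedback(build_feedback(rec, res.scores), "text"))
```

prints

```
category: hazardous_harmful | trial eligible: True
AUDIT 13 AUDIT-C 7 LDQ 15
Personalized feedback for demo-01
========================================

Your AUDIT score
----------------
Score: 13 (hazardous)
...
Estimated peak blood alcohol concentration
------------------------------------------
Peak BAC: 0.124 g/100 mL
...
Estimated monthly spend on alcohol
----------------------------------
AUD 297.00 per month
...
```

AUDIT-C = 3+2+2 = 7 puts this respondent in the hazardous/harmful band
(trial-eligible).  The BAC is 10 drinks × 10 g / (80 kg × 0.68 × 10) −
0.015 × 4 h ≈ 0.124 g/100 mL; the spend is 10.8 drinking days/month × 5.5
drinks × AUD 5.  Because his typical occasion (5.5 drinks) exceeds the
4-drink guideline, the normative bars are shown; a below-guideline drinker
would see them suppressed.

From the shell:

```bash
esbi simulate --n 172 --seed 1 --out-dir sim   # synthetic cohort
esbi screen sim/responses.csv --out screening.csv
esbi summarize --flow sim/flow.csv --tables
```

## Documentation

`docs/methods.md` describes the models, the default parameters and where
they come from, the synthetic generator's assumptions, and known
limitations.  Instrument wording and all feedback text/norm values live in
editable YAML under `src/esbi/data/` (the trauma-scale items and the norm
table are clearly-labelled placeholders).
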