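schema_version: 1
# Default feedback configuration.  All messages, norms and tier texts here
# are package-authored placeholders (clearly labelled), editable without
# touching code.  Quantitative defaults: 2009 Australian guidelines
# (<=2 standard drinks/day, <=4 per occasion, 10 g ethanol per standard
# drink), Widmark constants r=0.68 (male) / 0.55 (female), elimination
# 0.015 g/100 mL per hour.
guidelines:
  single_occasion_limit: 4.0   # standard drinks per occasion
  daily_limit: 2.0             # standard drinks per day
  standard_drink_grams: 10.0   # grams ethanol per Australian standard drink
bac:
  distribution_ratio:
    male: 0.68
    female: 0.55
  elimination_rate_per_hour: 0.015  # g/100 mL per hour
price_per_drink: 5.0  # AUD per standard drink, used for monthly-spend estimate
currency: AUD
# Midpoints mapping AUDIT item 1 (drinking frequency) and item 2 (typical
# drinks per drinking day) option indices to numbers used in the spend and
# consumption-comparison calculations.
frequency_days_per_month: [0.0, 0.5, 3.0, 10.8, 22.0]
typical_drinks_midpoint: [1.5, 3.5, 5.5, 8.0, 10.0]
# PLACEHOLDER norm table (synthetic values, not national survey estimates):
# typical-occasion and weekly standard drinks by gender and age group.
norms:
  male:
    "18-34": {typical_occasion_drinks: 5.0, weekly_drinks: 12.0}
    "35-54": {typical_occasion_drinks: 4.0, weekly_drinks: 11.0}
    "55+": {typical_occasion_drinks: 3.0, weekly_drinks: 9.0}
  female:
    "18-34": {typical_occasion_drinks: 4.0, weekly_drinks: 8.0}
    "35-54": {typical_occasion_drinks: 3.0, weekly_drinks: 6.0}
    "55+": {typical_occasion_drinks: 2.0, weekly_drinks: 4.0}
audit_bands:
  - {lo: 0, hi: 7, label: lower risk,
     message: "PLACEHOLDER: Your score suggests you are at lower risk of alcohol-related harm."}
  - {lo: 8, hi: 15, label: hazardous,
     message: "PLACEHOLDER: Your score suggests a hazardous pattern of drinking."}
  - {lo: 16, hi: 19, label: harmful,
     message: "PLACEHOLDER: Your score suggests drinking that is already harmful to your health."}
  - {lo: 20, hi: 40, label: possible dependence,
     message: "PLACEHOLDER: Your score suggests possible alcohol dependence; consider seeking advice."}
ldq_bands:
  - {lo: 0, hi: 0, label: no dependence,
     message: "PLACEHOLDER: Your answers show no signs of alcohol dependence."}
  - {lo: 1, hi: 10, label: low dependence,
     message: "PLACEHOLDER: Your answers show a low level of alcohol dependence."}
  - {lo: 11, hi: 20, label: moderate dependence,
     message: "PLACEHOLDER: Your answers show a moderate level of alcohol dependence."}
  - {lo: 21, hi: 30, label: high dependence,
     message: "PLACEHOLDER: Your answers show a high level of alcohol dependence; seeking support is recommended."}
# Behavioural/physiological tiers by estimated peak BAC (g/100 mL).
# Placeholder texts; thresholds are lower bounds.
bac_tiers:
  - {threshold: 0.0, text: "PLACEHOLDER: Little or no impairment expected at this level."}
  - {threshold: 0.05, text: "PLACEHOLDER: Impaired judgement and slowed reactions; above the legal driving limit."}
  - {threshold: 0.10, text: "PLACEHOLDER: Clearly impaired coordination and reaction time."}
  - {threshold: 0.20, text: "PLACEHOLDER: Severe impairment; risk of injury and memory loss."}
  - {threshold: 0.30, text: "PLACEHOLDER: Risk of loss of consciousness; medical emergency territory."}
info_pages:
  - title: About alcohol
    body: "PLACEHOLDER: Information about alcohol and the consequences of unhealthy alcohol consumption."
  - title: Tips for reducing risk
    body: "PLACEHOLDER: Practical tips for reducing the risk of alcohol-related harm."
  - title: Sources of support
    body: "PLACEHOLDER: Contact details for local services that support people with drinking problems."
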