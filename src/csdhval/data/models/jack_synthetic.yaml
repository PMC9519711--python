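# Jack risk-factor score — 2-month hematoma recurrence.
#
# Predictor categorizations follow the published model description:
# age (<= 80 / > 80) — note the boundary differs from the SHE score's
# (< 80 / >= 80) — hematoma volume in mL (<= 160 / > 160), and septations.
#
# SYNTHETIC PLACEHOLDERS: point values and the score -> probability table
# are NOT the published ones; transcribe them from the development
# publication before any clinical interpretation.
name: jack
outcome: recurrence_2m
source: >
  Categorizations from the published validation summary of the Jack
  risk-factor scoring system (Jack et al., 2014); point values and risk
  table are synthetic placeholders.
predictors:
  - field: age
    kind: threshold_category
    categories:
      - {label: "<=80", max: 80, max_inclusive: true, points: 0}
      - {label: ">80", min: 80, min_inclusive: false, points: 1}
  - field: volume_ml
    kind: threshold_category
    categories:
      - {label: "<=160", max: 160, max_inclusive: true, points: 0}
      - {label: ">160", min: 160, min_inclusive: false, points: 1}
  - field: septations
    kind: named_category
    categories:
      - {label: "absent", values: [false], points: 0}
      - {label: "present", values: [true], points: 1}
risk_map:
  kind: score_table
  table:
    - {score: 0, probability: 0.06}
    - {score: 1, probability: 0.12}
    - {score: 2, probability: 0.25}
    - {score: 3, probability: 0.40}
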