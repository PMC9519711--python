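# Subdural Hematoma in the Elderly (SHE) score — 30-day mortality.
#
# Predictor categorizations follow the published model description:
# age (< 80 / >= 80), admission GCS (3-4 / 5-12 / 13-15), hematoma
# volume in mL (< 50 / >= 50); developed in patients aged > 65.
#
# SYNTHETIC PLACEHOLDERS: the per-category point values and the
# score -> probability table below are NOT the published ones (they are
# printed only in the development publication). Replace them with
# transcribed values before any clinical interpretation. The evaluation
# engine is entirely data-driven, so only this file needs editing.
name: alford_she
outcome: mortality_30d
target_population:
  field: age
  op: ">"
  value: 65
source: >
  Categorizations from the published validation summary of the SHE score
  (Alford et al., 2020); point values and risk table are synthetic
  placeholders.
predictors:
  - field: age
    kind: threshold_category
    categories:
      - {label: "<80", max: 80, max_inclusive: false, points: 0}
      - {label: ">=80", min: 80, min_inclusive: true, points: 1}
  - field: gcs_category
    kind: named_category
    categories:
      - {label: "13-15", values: ["13-15"], points: 0}
      - {label: "5-12", values: ["5-12"], points: 1}
      - {label: "3-4", values: ["3-4"], points: 2}
  - field: volume_ml
    kind: threshold_category
    categories:
      - {label: "<50", max: 50, max_inclusive: false, points: 0}
      - {label: ">=50", min: 50, min_inclusive: true, points: 1}
risk_map:
  kind: score_table
  table:
    - {score: 0, probability: 0.03}
    - {score: 1, probability: 0.10}
    - {score: 2, probability: 0.25}
    - {score: 3, probability: 0.50}
    - {score: 4, probability: 0.75}
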