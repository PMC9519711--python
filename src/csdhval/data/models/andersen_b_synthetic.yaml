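# Andersen model B (preoperative nomogram) — 3-month recurrence.
#
# Predictors follow the published model description: hematoma volume,
# hematoma density, history of hypertension. Consumed as a nomogram
# lookup (see andersen_a_synthetic.yaml).
#
# SYNTHETIC PLACEHOLDERS: all numeric point values and the total-points ->
# probability curve are NOT the published ones; transcribe them before
# any clinical interpretation.
name: andersen_b
outcome: recurrence_3m
source: >
  Predictor set from the published validation summary of Andersen's
  preoperative model (Andersen et al., 2018); nomogram point values and
  risk curve are synthetic placeholders.
predictors:
  - field: volume_ml
    kind: continuous_points
    anchors:
      - {value: 0, points: 0}
      - {value: 100, points: 30}
      - {value: 200, points: 60}
      - {value: 300, points: 85}
  - field: density
    kind: named_category
    categories:
      - {label: "homogeneous", values: ["homogeneous"], points: 0}
      - {label: "membranous", values: ["membranous"], points: 12}
      - {label: "mixed", values: ["mixed"], points: 25}
      - {label: "separated", values: ["separated"], points: 35}
  - field: hypertension
    kind: named_category
    categories:
      - {label: "no", values: [false], points: 0}
      - {label: "yes", values: [true], points: 15}
risk_map:
  kind: nomogram_curve
  curve:
    - {points: 0, probability: 0.03}
    - {points: 35, probability: 0.07}
    - {points: 70, probability: 0.14}
    - {points: 105, probability: 0.28}
    - {points: 135, probability: 0.45}
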