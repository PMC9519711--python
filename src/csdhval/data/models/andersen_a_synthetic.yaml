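# Andersen model A (postoperative nomogram) — 3-month recurrence.
#
# Predictors follow the published model description: hematoma volume,
# hematoma density, history of hypertension, drainage time, drain type,
# and postoperative surgical complications. The model is consumed as a
# nomogram lookup: per-predictor points (volume on a continuous axis read
# by linear interpolation) summed and mapped to a probability along the
# total-points curve.
#
# SYNTHETIC PLACEHOLDERS: all numeric point values and the total-points ->
# probability curve are NOT the published ones (they live in the
# development publication / supplement); transcribe them before any
# clinical interpretation.
name: andersen_a
outcome: recurrence_3m
source: >
  Predictor set from the published validation summary of Andersen's
  postoperative model (Andersen et al., 2018); nomogram point values and
  risk curve are synthetic placeholders.
predictors:
  - field: volume_ml
    kind: continuous_points
    anchors:
      - {value: 0, points: 0}
      - {value: 100, points: 25}
      - {value: 200, points: 50}
      - {value: 300, points: 70}
  - field: density
    kind: named_category
    categories:
      - {label: "homogeneous", values: ["homogeneous"], points: 0}
      - {label: "membranous", values: ["membranous"], points: 10}
      - {label: "mixed", values: ["mixed"], points: 20}
      - {label: "separated", values: ["separated"], points: 30}
  - field: hypertension
    kind: named_category
    categories:
      - {label: "no", values: [false], points: 0}
      - {label: "yes", values: [true], points: 12}
  - field: drainage_time
    kind: named_category
    categories:
      - {label: "no_drain", values: ["no_drain"], points: 25}
      - {label: "1-24h", values: ["1-24h"], points: 15}
      - {label: "24-48h", values: ["24-48h"], points: 5}
      - {label: ">48h", values: [">48h"], points: 0}
  - field: drain_type
    kind: named_category
    categories:
      - {label: "no_drain", values: ["no_drain"], points: 20}
      - {label: "subdural", values: ["subdural"], points: 0}
      - {label: "subgaleal_subperiosteal", values: ["subgaleal_subperiosteal"], points: 8}
  - field: postop_complication
    kind: named_category
    categories:
      - {label: "no", values: [false], points: 0}
      - {label: "yes", values: [true], points: 15}
risk_map:
  kind: nomogram_curve
  curve:
    - {points: 0, probability: 0.02}
    - {points: 40, probability: 0.06}
    - {points: 80, probability: 0.15}
    - {points: 120, probability: 0.30}
    - {points: 160, probability: 0.50}
    - {points: 200, probability: 0.70}
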