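"""Data dictionary for the patient cohort table.

One row per patient; an empty cell means missing. Every field may be
individually missing unless noted. Categorical domains here are the single
source of truth for both cohort loading and model-definition validation.
"""

from __future__ import annotations

REGIONS = ("Amsterdam", "North-East", "Rotterdam")

TREATMENTS = ("wait_and_see", "surgery", "surgery_plus_dexamethasone", "dexamethasone")

GCS_CATEGORIES = ("3-4", "5-12", "13-15")

HEMATOMA_TYPES = (
    "homogeneous",
    "membranous",
    "trabecular",
    "mixed",
    "separated",
    "laminar",
    "other",
)

#: hematoma types from which presence of septations can be read off the name
SEPTATED_TYPES = frozenset({"membranous", "trabecular"})

DENSITIES = ("homogeneous", "membranous", "mixed", "separated")

DRAINAGE_TIMES = ("no_drain", "1-24h", "24-48h", ">48h")

DRAIN_TYPES = ("no_drain", "subdural", "subgaleal_subperiosteal")

LATERALITIES = ("unilateral", "bilateral")

SEXES = ("male", "female")

OUTCOME_COLUMNS = ("mortality_30d", "recurrence_2m", "recurrence_3m")

BOOLEAN_COLUMNS = ("septations", "hypertension", "postop_complication") + OUTCOME_COLUMNS

NUMERIC_COLUMNS = ("age", "volume_ml")

CATEGORICAL_DOMAINS: dict[str, tuple[str, ...]] = {
    "region": REGIONS,
    "treatment": TREATMENTS,
    "sex": SEXES,
    "gcs_category": GCS_CATEGORIES,
    "hematoma_type": HEMATOMA_TYPES,
    "density": DENSITIES,
    "drainage_time": DRAINAGE_TIMES,
    "drain_type": DRAIN_TYPES,
    "laterality": LATERALITIES,
}

#: domains usable in model-definition named categories (booleans included)
FIELD_DOMAINS: dict[str, tuple[object, ...]] = {
    **CATEGORICAL_DOMAINS,
    **{col: (False, True) for col in BOOLEAN_COLUMNS},
}

COHORT_COLUMNS = (
    ("patient_id",)
    + ("region", "treatment", "sex", "laterality")
    + NUMERIC_COLUMNS
    + ("gcs_category", "hematoma_type", "density", "drainage_time", "drain_type")
    + ("septations", "hypertension", "postop_complication")
    + OUTCOME_COLUMNS
)
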