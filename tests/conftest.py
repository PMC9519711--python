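"""Shared fixtures: toy cohorts, toy model definitions, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from csdhval import preprocess
from csdhval.model_registry import build_model_spec


# ---------------------------------------------------------------------------
# brute-force reference implementations (kept independent of the package's
# optimized code paths: direct pair counting via outer products)
# ---------------------------------------------------------------------------


def c_index_bruteforce(p, y) -> float:
    """Concordant + half-tied pairs over all event/non-event pairs."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    pe, pn = p[y == 1], p[y == 0]
    diff = pe[:, None] - pn[None, :]
    num = float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
    return num / (len(pe) * len(pn))


def mbc_bruteforce(p) -> float:
    """Pairwise definition of the model-based concordance over all pairs."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    num = den = 0.0
    iu, ju = np.triu_indices(n, k=1)
    hi = np.maximum(p[iu], p[ju])
    lo = np.minimum(p[iu], p[ju])
    informative = hi * (1 - lo) + lo * (1 - hi)
    ties = hi == lo
    num = float(np.sum(np.where(ties, informative / 2.0, hi * (1 - lo))))
    den = float(np.sum(informative))
    return 0.5 if den == 0 else num / den


# ---------------------------------------------------------------------------
# toy model definitions
# ---------------------------------------------------------------------------


def toy_score_raw(points_age=(0, 1), points_gcs=(2, 1, 0), points_vol=(0, 1)):
    """Raw dict for a 3-predictor score model (age / GCS / volume)."""
    return {
        "name": "toy_score",
        "outcome": "mortality_30d",
        "predictors": [
            {
                "field": "age",
                "kind": "threshold_category",
                "categories": [
                    {"label": "<80", "max": 80, "max_inclusive": False,
                     "points": points_age[0]},
                    {"label": ">=80", "min": 80, "min_inclusive": True,
                     "points": points_age[1]},
                ],
            },
            {
                "field": "gcs_category",
                "kind": "named_category",
                "categories": [
                    {"label": "3-4", "values": ["3-4"], "points": points_gcs[0]},
                    {"label": "5-12", "values": ["5-12"], "points": points_gcs[1]},
                    {"label": "13-15", "values": ["13-15"], "points": points_gcs[2]},
                ],
            },
            {
                "field": "volume_ml",
                "kind": "threshold_category",
                "categories": [
                    {"label": "<50", "max": 50, "max_inclusive": False,
                     "points": points_vol[0]},
                    {"label": ">=50", "min": 50, "min_inclusive": True,
                     "points": points_vol[1]},
                ],
            },
        ],
        "risk_map": {
            "kind": "score_table",
            "table": [
                {"score": s, "probability": p}
                for s, p in [(0, 0.03), (1, 0.08), (2, 0.18), (3, 0.35), (4, 0.55)]
            ],
        },
    }


def toy_nomogram_raw():
    """Raw dict for a 2-predictor nomogram model (volume axis + a binary)."""
    return {
        "name": "toy_nomogram",
        "outcome": "recurrence_3m",
        "predictors": [
            {
                "field": "volume_ml",
                "kind": "continuous_points",
                "anchors": [
                    {"value": 0, "points": 0},
                    {"value": 100, "points": 40},
                    {"value": 200, "points": 60},
                ],
            },
            {
                "field": "hypertension",
                "kind": "named_category",
                "categories": [
                    {"label": "no", "values": [False], "points": 0},
                    {"label": "yes", "values": [True], "points": 10},
                ],
            },
        ],
        "risk_map": {
            "kind": "nomogram_curve",
            "curve": [
                {"points": 0, "probability": 0.02},
                {"points": 35, "probability": 0.10},
                {"points": 70, "probability": 0.30},
            ],
        },
    }


@pytest.fixture
def toy_score_spec():
    return build_model_spec(toy_score_raw())


@pytest.fixture
def toy_nomogram_spec():
    return build_model_spec(toy_nomogram_raw())


# ---------------------------------------------------------------------------
# toy cohorts
# ---------------------------------------------------------------------------


def make_cohort(rows: list[dict]) -> pd.DataFrame:
    """Cohort frame with data-dictionary dtypes from sparse row dicts."""
    defaults = {
        "patient_id": None,
        "region": "North-East",
        "treatment": "surgery",
        "sex": "male",
        "laterality": "unilateral",
        "age": 70.0,
        "volume_ml": 100.0,
        "gcs_category": "13-15",
        "hematoma_type": "homogeneous",
        "density": "homogeneous",
        "drainage_time": "1-24h",
        "drain_type": "subdural",
        "septations": False,
        "hypertension": False,
        "postop_complication": False,
        "mortality_30d": False,
        "recurrence_2m": False,
        "recurrence_3m": False,
    }
    filled = []
    for i, row in enumerate(rows):
        r = {**defaults, **row}
        if r["patient_id"] is None:
            r["patient_id"] = f"T{i:03d}"
        filled.append(r)
    return preprocess.coerce_cohort(pd.DataFrame(filled))
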