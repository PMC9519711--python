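"""Cohort loading, predictor/outcome derivation, and analysis-set selection.

The cohort is a pandas DataFrame, one row per patient, columns per
:mod:`csdhval.schema` (empty cell = missing). Outcomes are fixed-window
binaries derived from day offsets relative to diagnosis/treatment; the
windows are module constants because month lengths are a convention, not a
measurement:

* 30-day mortality, day 30 inclusive;
* 2-month recurrence  = any retreatment within ``DAYS_2M`` = 61 days;
* 3-month recurrence  = any retreatment within ``DAYS_3M`` = 92 days.

Analysis sets implement the two validation modes: *complete case* (all model
predictors and the outcome observed) and *imputed* (outcome observed; missing
predictors left for multiple imputation — missing outcomes are never
imputed, those records simply drop out).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from . import schema
from .model_registry import ModelSpec, TargetPopulation

logger = logging.getLogger(__name__)

#: outcome window lengths in days (configurable conventions)
DAYS_30D = 30
DAYS_2M = 61
DAYS_3M = 92


class DataError(ValueError):
    """Raw field values violate a precondition (e.g. negative day offset)."""


class EmptyAnalysisSetError(ValueError):
    """Selection produced zero records; surfaced explicitly so downstream
    statistics never divide by zero silently."""


# ---------------------------------------------------------------------------
# predictor derivation
# ---------------------------------------------------------------------------


def abc2_volume(a: float, b: float, c: float) -> float:
    """Hematoma volume (mL) from three orthogonal diameters (cm), a*b*c/2."""
    if a <= 0 or b <= 0 or c <= 0:
        raise DataError(f"diameters must be positive, got ({a}, {b}, {c})")
    return a * b * c / 2.0


def derive_septations(hematoma_type):
    """Septations from the hematoma-type label.

    Only membranous/trabecular hematomas can be read as septated from the
    type name alone; other *named* types are scored as not containing
    septations. Unknown labels and missing types propagate as missing —
    never silently "no septations".

    Accepts a scalar or a pandas Series (returns nullable-boolean Series).
    """
    if isinstance(hematoma_type, pd.Series):
        out = pd.Series(pd.NA, index=hematoma_type.index, dtype="boolean")
        known = hematoma_type.isin(list(schema.HEMATOMA_TYPES))
        out[known] = hematoma_type[known].isin(list(schema.SEPTATED_TYPES))
        return out
    if pd.isna(hematoma_type):
        return pd.NA
    if hematoma_type not in schema.HEMATOMA_TYPES:
        logger.warning("unknown hematoma type %r treated as missing", hematoma_type)
        return pd.NA
    return hematoma_type in schema.SEPTATED_TYPES


def define_outcomes(
    death_day: float | None, retreatment_days: Sequence[float] | None
) -> dict[str, bool | None]:
    """Fixed-window outcomes from raw day offsets.

    ``death_day`` is days from diagnosis to death (None if alive/unknown);
    ``retreatment_days`` are day offsets of retreatment events (reoperation
    or renewed dexamethasone), None if follow-up is missing.
    """
    events = list(retreatment_days) if retreatment_days is not None else None
    if death_day is not None and death_day < 0:
        raise DataError(f"negative death day offset {death_day}")
    if events is not None and any(d < 0 for d in events):
        raise DataError(f"negative retreatment day offset in {events}")
    mortality = None if death_day is None else death_day <= DAYS_30D
    rec2 = None if events is None else any(d <= DAYS_2M for d in events)
    rec3 = None if events is None else any(d <= DAYS_3M for d in events)
    return {
        "mortality_30d": mortality,
        "recurrence_2m": rec2,
        "recurrence_3m": rec3,
    }


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------

_DTYPES = (
    {c: "Float64" for c in schema.NUMERIC_COLUMNS}
    | {c: "boolean" for c in schema.BOOLEAN_COLUMNS}
    | {c: "string" for c in schema.CATEGORICAL_DOMAINS}
    | {"patient_id": "string"}
)


def coerce_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the data-dictionary dtypes and null out-of-domain categories."""
    df = df.copy()
    for col, dtype in _DTYPES.items():
        if col in df.columns:
            df[col] = df[col].astype(dtype)
    for col, domain in schema.CATEGORICAL_DOMAINS.items():
        if col in df.columns:
            bad = df[col].notna() & ~df[col].isin(list(domain))
            if bad.any():
                logger.warning(
                    "%d out-of-domain value(s) in %r treated as missing",
                    int(bad.sum()),
                    col,
                )
                df.loc[bad, col] = pd.NA
    if "age" in df.columns and (df["age"].dropna() <= 0).any():
        raise DataError("non-positive age in cohort")
    if "volume_ml" in df.columns and (df["volume_ml"].dropna() <= 0).any():
        raise DataError("non-positive hematoma volume in cohort")
    return df


def load_cohort(path) -> pd.DataFrame:
    """Read a delimited cohort table (comma-separated, header row)."""
    df = pd.read_csv(path)
    return coerce_cohort(df)


def save_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# analysis-set selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Subgroup:
    """Named predicate over patient records, e.g. the development-study
    eligibility subgroup (age > 65)."""

    label: str
    predicate: Callable[[pd.DataFrame], np.ndarray]

    @classmethod
    def from_target_population(cls, tp: TargetPopulation) -> "Subgroup":
        return cls(label=tp.label, predicate=tp.mask)


@dataclass
class AnalysisSet:
    """Records selected for one model under one validation mode."""

    model: str
    records: pd.DataFrame
    selection: str  # complete_case | imputed
    subgroup: str | None = None
    region: str | None = None

    @property
    def n(self) -> int:
        return len(self.records)


def select_analysis_set(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    selection: str = "complete_case",
    subgroup: Subgroup | None = None,
    region: str | None = None,
) -> AnalysisSet:
    """Select the records a model is validated on.

    Always applied: unilateral-hematoma eligibility (when a laterality
    column is present) and availability of the model's outcome. Complete-case
    selection additionally requires every model predictor to be observed.
    Subgroup predicates evaluate to False on records where the subgroup field
    is missing. Raises :class:`EmptyAnalysisSetError` on an empty result.
    """
    if selection not in ("complete_case", "imputed"):
        raise ValueError(f"unknown selection {selection!r}")
    df = cohort
    counts = {"input": len(df)}
    if "laterality" in df.columns:
        df = df[df["laterality"] == "unilateral"]
    counts["unilateral"] = len(df)
    if region is not None:
        if region not in schema.REGIONS:
            raise ValueError(f"unknown region {region!r}")
        df = df[df["region"] == region]
    if subgroup is not None:
        df = df[subgroup.predicate(df)]
    counts["eligible"] = len(df)
    df = df[df[spec.outcome].notna()]
    counts["outcome_available"] = len(df)
    if selection == "complete_case":
        mask = np.ones(len(df), dtype=bool)
        for col in spec.required_fields:
            mask &= df[col].notna().to_numpy()
        df = df[mask]
    counts["selected"] = len(df)
    logger.info(
        "analysis set %s/%s region=%s subgroup=%s: %s",
        spec.name,
        selection,
        region,
        subgroup.label if subgroup else None,
        counts,
    )
    if len(df) == 0:
        raise EmptyAnalysisSetError(
            f"empty analysis set for model '{spec.name}' "
            f"(selection={selection}, region={region}, "
            f"subgroup={subgroup.label if subgroup else None})"
        )
    return AnalysisSet(
        model=spec.name,
        records=df.copy(),
        selection=selection,
        subgroup=subgroup.label if subgroup else None,
        region=region,
    )
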