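"""Synthetic cohorts with the statistical structure of a multi-region
chronic-subdural-hematoma registry.

The generator emulates the marginal distributions of a three-region Dutch
registry of unilateral CSDH patients (the defaults below: age 73.0 (SD 12.4)
years, 73.5% male, hematoma volume 112.6 (SD 54.5) mL, category frequencies
for GCS, density, drainage, treatment, and outcome prevalences of 3.9%
30-day mortality and 8.9%/9.5% recurrence at 2/3 months), a configurable
*true* logistic outcome model for parameter-recovery experiments, and a
missingness mechanism with per-column MCAR rates plus region-level
structural missingness (a variable never collected in one region).

Predictors are drawn independently — the registry's joint distribution is
not published — so generated data are suited to testing the validation
machinery, not to clinical inference. Outcome nesting is enforced by
construction: 2-month recurrences are a random subset of 3-month
recurrences, thinned to the registry's event-count ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from . import schema
from .model_registry import expit

TWO_OF_THREE_MONTH_RATIO = 155.0 / 164.0  # observed 2m / 3m recurrence events


class ConfigError(ValueError):
    pass


class SolverError(RuntimeError):
    """The requested marginal prevalence cannot be reached by any intercept."""


@dataclass(frozen=True)
class TrueOutcomeModel:
    """Logistic data-generating model for one outcome.

    ``terms`` map design columns to coefficients. A key is either a numeric
    column (centered at ``centers``), a boolean column (0/1), or an
    indicator ``"column=value"``. The intercept is solved numerically so the
    cohort's expected prevalence hits ``target_prevalence``; coefficient
    values are arbitrary, documented experiment settings — nothing here is a
    claim about CSDH biology.
    """

    terms: Mapping[str, float]
    target_prevalence: float

    def __post_init__(self):
        if not (0.0 < self.target_prevalence < 1.0):
            raise SolverError(
                f"target prevalence {self.target_prevalence} not attainable "
                "(must be strictly inside (0, 1))"
            )


#: centering constants for numeric terms of the true models
CENTERS = {"age": 73.0, "volume_ml": 112.6}

DEFAULT_TRUE_MODELS: dict[str, TrueOutcomeModel] = {
    "mortality_30d": TrueOutcomeModel(
        terms={"age": 0.05, "volume_ml": 0.006, "gcs_category=5-12": 0.9,
               "gcs_category=3-4": 2.0},
        target_prevalence=0.039,
    ),
    "recurrence_3m": TrueOutcomeModel(
        terms={"volume_ml": 0.004, "septations": 0.4, "hypertension": 0.3,
               "density=separated": 0.5},
        target_prevalence=0.095,
    ),
}

#: per-column MCAR missingness rates mirroring the registry's missing shares
DEFAULT_MCAR_RATES: dict[str, float] = {
    "gcs_category": 0.065,
    "volume_ml": 0.466,
    "septations": 0.488,
    "hypertension": 0.229,
    "density": 0.454,
    "drainage_time": 0.569,
    "drain_type": 0.749,
    "postop_complication": 0.224,
}

#: outcome availability gaps (records drop from analysis, never imputed)
DEFAULT_OUTCOME_RATES: dict[str, float] = {
    "mortality_30d": 0.059,
    "recurrence_2m": 0.015,
    "recurrence_3m": 0.015,
}


@dataclass(frozen=True)
class MissingnessSpec:
    """MCAR rates per column plus (region, column) structural blanks."""

    mcar_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MCAR_RATES)
    )
    structural: tuple[tuple[str, str], ...] = ()
    outcome_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_RATES)
    )

    def __post_init__(self):
        for col, r in {**self.mcar_rates, **self.outcome_rates}.items():
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"missingness rate for '{col}' outside [0, 1]")
        for region, col in self.structural:
            if region not in schema.REGIONS:
                raise ConfigError(f"structural mask names unknown region {region!r}")


def _probs(name: str, p: Sequence[float]) -> tuple[float, ...]:
    p = tuple(float(x) for x in p)
    if any(x < 0 or x > 1 for x in p):
        raise ConfigError(f"{name}: probabilities outside [0, 1]")
    s = sum(p)
    if s <= 0:
        raise ConfigError(f"{name}: probabilities sum to zero")
    return tuple(x / s for x in p)  # renormalize printed frequencies


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults are the registry marginals."""

    n: int = 1760
    seed: int | None = None
    region_probs: tuple[float, ...] = (0.106, 0.547, 0.347)  # AM / NE / RO
    male_prob: float = 0.735
    age_mean: float = 73.0
    age_sd: float = 12.4
    age_bounds: tuple[float, float] = (18.0, 105.0)
    volume_mean: float = 112.6
    volume_sd: float = 54.5
    gcs_probs: tuple[float, ...] = (0.002, 0.118, 0.879)  # 3-4 / 5-12 / 13-15
    septations_prob: float = 0.372
    hypertension_prob: float = 0.161
    postop_complication_prob: float = 0.072
    density_probs: tuple[float, ...] = (0.523, 0.344, 0.004, 0.128)
    drainage_time_probs: tuple[float, ...] = (0.132, 0.507, 0.270, 0.091)
    drain_type_probs: tuple[float, ...] = (0.226, 0.369, 0.405)
    treatment_probs: tuple[float, ...] = (0.073, 0.472, 0.428, 0.027)
    true_models: Mapping[str, TrueOutcomeModel] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_MODELS)
    )
    recurrence_2m_ratio: float = TWO_OF_THREE_MONTH_RATIO
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)

    def __post_init__(self):
        if self.n < 0:
            raise ConfigError("cohort size must be non-negative")
        for name, p, k in (
            ("region_probs", self.region_probs, len(schema.REGIONS)),
            ("gcs_probs", self.gcs_probs, len(schema.GCS_CATEGORIES)),
            ("density_probs", self.density_probs, len(schema.DENSITIES)),
            ("drainage_time_probs", self.drainage_time_probs, len(schema.DRAINAGE_TIMES)),
            ("drain_type_probs", self.drain_type_probs, len(schema.DRAIN_TYPES)),
            ("treatment_probs", self.treatment_probs, len(schema.TREATMENTS)),
        ):
            if len(p) != k:
                raise ConfigError(f"{name}: expected {k} probabilities")
            _probs(name, p)
        for prob in (self.male_prob, self.septations_prob, self.hypertension_prob,
                     self.postop_complication_prob, self.recurrence_2m_ratio):
            if not (0.0 <= prob <= 1.0):
                raise ConfigError("Bernoulli probability outside [0, 1]")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Truncated-normal draws whose *post-truncation* mean equals ``mean``.

    Truncation shifts the mean of a plain truncated normal (noticeably for
    the volume distribution, cut at 0 about two SDs below center), so the
    location parameter is solved by root bracketing to keep the realized
    marginal on target.
    """

    def trunc_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(truncnorm.mean(a, b, loc=loc, scale=sd))

    lo_loc, hi_loc = mean - 3 * sd, mean + 3 * sd
    if trunc_mean(lo_loc) > mean or trunc_mean(hi_loc) < mean:  # pragma: no cover
        raise ConfigError(f"target mean {mean} unattainable within [{lo}, {hi}]")
    loc = brentq(lambda m: trunc_mean(m) - mean, lo_loc, hi_loc, xtol=1e-8)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


_UNSEPTATED_TYPES = ("homogeneous", "mixed", "separated", "laminar", "other")
_UNSEPTATED_TYPE_PROBS = (0.60, 0.10, 0.20, 0.05, 0.05)


def generate_cohort(config: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Draw ``config.n`` complete patient records from the marginals.

    All records are unilateral (the analysis population); hematoma type is
    drawn consistently with the septations flag so the type→septations
    derivation rule holds on generated data.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    df = pd.DataFrame(
        {
            "patient_id": pd.array([f"P{i:06d}" for i in range(n)], dtype="string"),
            "region": pd.array(
                rng.choice(schema.REGIONS, n, p=_probs("region", config.region_probs)),
                dtype="string",
            ),
            "treatment": pd.array(
                rng.choice(
                    schema.TREATMENTS, n, p=_probs("treatment", config.treatment_probs)
                ),
                dtype="string",
            ),
            "sex": pd.array(
                np.where(rng.random(n) < config.male_prob, "male", "female"),
                dtype="string",
            ),
            "laterality": pd.array(["unilateral"] * n, dtype="string"),
            "age": pd.array(
                _truncated_normal(
                    rng, config.age_mean, config.age_sd, *config.age_bounds, n
                ),
                dtype="Float64",
            ),
            "volume_ml": pd.array(
                _truncated_normal(
                    rng, config.volume_mean, config.volume_sd, 0.0, np.inf, n
                ),
                dtype="Float64",
            ),
            "gcs_category": pd.array(
                rng.choice(
                    schema.GCS_CATEGORIES, n, p=_probs("gcs", config.gcs_probs)
                ),
                dtype="string",
            ),
            "density": pd.array(
                rng.choice(schema.DENSITIES, n, p=_probs("density", config.density_probs)),
                dtype="string",
            ),
            "drainage_time": pd.array(
                rng.choice(
                    schema.DRAINAGE_TIMES,
                    n,
                    p=_probs("drainage_time", config.drainage_time_probs),
                ),
                dtype="string",
            ),
            "drain_type": pd.array(
                rng.choice(
                    schema.DRAIN_TYPES, n, p=_probs("drain_type", config.drain_type_probs)
                ),
                dtype="string",
            ),
            "septations": pd.array(
                rng.random(n) < config.septations_prob, dtype="boolean"
            ),
            "hypertension": pd.array(
                rng.random(n) < config.hypertension_prob, dtype="boolean"
            ),
            "postop_complication": pd.array(
                rng.random(n) < config.postop_complication_prob, dtype="boolean"
            ),
        }
    )
    septated = df["septations"].to_numpy(dtype=bool, na_value=False)
    types = np.empty(n, dtype=object)
    types[septated] = rng.choice(("membranous", "trabecular"), int(septated.sum()))
    types[~septated] = rng.choice(
        _UNSEPTATED_TYPES, int((~septated).sum()), p=_UNSEPTATED_TYPE_PROBS
    )
    df["hematoma_type"] = pd.array(types, dtype="string")
    return df


def design_column(df: pd.DataFrame, key: str) -> np.ndarray:
    """Resolve a true-model term key into a numeric design column."""
    if "=" in key:
        col, val = key.split("=", 1)
        if col not in df.columns:
            raise ConfigError(f"true-model term references unknown column '{col}'")
        return (df[col] == val).to_numpy(dtype=float)
    if key not in df.columns:
        raise ConfigError(f"true-model term references unknown column '{key}'")
    s = df[key]
    if key in schema.NUMERIC_COLUMNS:
        if s.isna().any():
            raise ConfigError(f"true-model predictor '{key}' has missing values")
        return s.to_numpy(dtype=float) - CENTERS.get(key, 0.0)
    return s.to_numpy(dtype=float, na_value=np.nan)


def linear_predictor(df: pd.DataFrame, model: TrueOutcomeModel) -> np.ndarray:
    """Interceptless linear predictor of a true outcome model."""
    eta = np.zeros(len(df))
    for key, coef in model.terms.items():
        eta += coef * design_column(df, key)
    if np.any(np.isnan(eta)):
        raise ConfigError("true-model predictors must be complete")
    return eta


def solve_intercept(eta: np.ndarray, target: float, tol: float = 1e-6) -> float:
    """Intercept b0 with mean(expit(b0 + eta)) = target, by root bracketing."""
    if not (0.0 < target < 1.0):
        raise SolverError(f"prevalence target {target} not attainable")

    def gap(b0):
        return float(np.mean(expit(b0 + eta))) - target

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:  # pragma: no cover - 40 logits is ~1e-18
        raise SolverError(f"prevalence target {target} outside attainable range")
    return float(brentq(gap, lo, hi, xtol=tol))


def generate_outcomes(
    cohort: pd.DataFrame,
    true_models: Mapping[str, TrueOutcomeModel] | None = None,
    seed: int | None = None,
    rng=None,
    recurrence_2m_ratio: float = TWO_OF_THREE_MONTH_RATIO,
) -> pd.DataFrame:
    """Draw outcomes from the true logistic models.

    Mortality and 3-month recurrence are Bernoulli in their model's risk;
    2-month recurrence is a thinned subset of 3-month recurrence (enforcing
    nesting) at the configured event-count ratio.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if true_models is None:
        true_models = DEFAULT_TRUE_MODELS
    df = cohort.copy()
    risks: dict[str, np.ndarray] = {}
    for outcome in ("mortality_30d", "recurrence_3m"):
        model = true_models[outcome]
        eta = linear_predictor(df, model)
        b0 = solve_intercept(eta, model.target_prevalence)
        risks[outcome] = expit(b0 + eta)
        df[outcome] = pd.array(rng.random(len(df)) < risks[outcome], dtype="boolean")
    df["recurrence_2m"] = pd.array(
        df["recurrence_3m"].to_numpy(dtype=bool, na_value=False)
        & (rng.random(len(df)) < recurrence_2m_ratio),
        dtype="boolean",
    )
    df.attrs["true_risks"] = risks
    return df


def apply_missingness(
    cohort: pd.DataFrame,
    spec: MissingnessSpec | None = None,
    seed: int | None = None,
    rng=None,
) -> pd.DataFrame:
    """Blank cells MCAR per column, structurally per (region, column), and
    outcomes at their availability-gap rates.

    Raises :class:`ConfigError` if masking would leave a predictor column
    with zero observed values cohort-wide (which no imputation model could
    repair).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if spec is None:
        spec = MissingnessSpec()
    df = cohort.copy()
    n = len(df)
    for col, rate in spec.mcar_rates.items():
        if col not in df.columns:
            raise ConfigError(f"MCAR rate names unknown column '{col}'")
        df.loc[rng.random(n) < rate, col] = pd.NA
    for region, col in spec.structural:
        if col not in df.columns:
            raise ConfigError(f"structural mask names unknown column '{col}'")
        df.loc[df["region"] == region, col] = pd.NA
    for col, rate in spec.outcome_rates.items():
        if col in df.columns:
            df.loc[rng.random(n) < rate, col] = pd.NA
    masked = set(spec.mcar_rates) | {c for _, c in spec.structural}
    dead = [c for c in masked if n > 0 and df[c].isna().all()]
    if dead:
        raise ConfigError(
            f"masking left column(s) {dead} with no observed values anywhere"
        )
    return df


def simulate(config: SyntheticConfig) -> pd.DataFrame:
    """Full generator: marginals → true-model outcomes → missingness.

    One seed drives three independent sub-streams so components can be
    regenerated in isolation.
    """
    ss = np.random.SeedSequence(config.seed)
    s_cohort, s_outcome, s_missing = ss.spawn(3)
    df = generate_cohort(config, rng=np.random.default_rng(s_cohort))
    df = generate_outcomes(
        df,
        config.true_models,
        rng=np.random.default_rng(s_outcome),
        recurrence_2m_ratio=config.recurrence_2m_ratio,
    )
    return apply_missingness(
        df, config.missingness, rng=np.random.default_rng(s_missing)
    )
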