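"""Multiple imputation by chained equations and Rubin's-rules pooling.

Missing predictors are imputed with chained equations (statsmodels
``MICEData``): each incomplete variable is regressed on all others and
imputed by predictive mean matching with Bayesian parameter perturbation,
so imputed values are always observed donor values — binary and categorical
variables (entered as integer codes) stay in-domain. Hospital region enters
every conditional model as indicator columns, so a variable that was never
collected in one region is imputed from the other regions' data. Outcome
columns are never imputed: analysis sets exclude outcome-missing records
upstream, and this module refuses cohorts whose outcome column still has
holes.

Validation statistics computed on each completed dataset are combined with
Rubin's rules: pooled estimate = mean, total variance
``T = W + (1 + 1/m) B`` (within + inflated between), CI via the
t-distribution with Barnard–Rubin degrees of freedom. Bounded statistics
(the C-index) are pooled on the logit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit as _expit
from scipy.special import logit as _logit
from scipy.stats import norm, t as t_dist
from statsmodels.imputation.mice import MICEData

from . import schema
from .metrics import (
    EstimateWithCI,
    ValidationResult,
    calibration_in_the_large,
    calibration_slope,
    concordance,
    model_based_concordance,
)
from .model_registry import PROB_CLIP, ModelSpec, predict_probabilities

Z975 = float(norm.ppf(0.975))


class ImputationError(RuntimeError):
    pass


class OutcomeImputationError(ImputationError):
    """An outcome column with missing values reached the imputer."""


class UnimputableVariableError(ImputationError):
    """A variable has no observed values anywhere in the cohort."""


class PoolingError(ValueError):
    pass


@dataclass(frozen=True)
class ImputationConfig:
    """Chained-equations settings.

    ``m`` completed datasets from independent chains, each run for
    ``iterations`` cycles over the incomplete variables; predictive mean
    matching draws from ``k_pmm`` nearest donors. The seed fully determines
    the stack.
    """

    m: int = 10
    iterations: int = 10
    k_pmm: int = 5
    seed: int | None = None

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need at least m=2 imputations")
        if self.iterations < 1 or self.k_pmm < 1:
            raise ValueError("iterations and k_pmm must be positive")


@dataclass
class ImputedStack:
    """m completed cohorts plus per-cell provenance."""

    datasets: list[pd.DataFrame]
    imputed_mask: pd.DataFrame  # True where a cell was filled in
    config: ImputationConfig

    @property
    def m(self) -> int:
        return len(self.datasets)


# ---------------------------------------------------------------------------
# encoding helpers: MICEData needs an all-float frame with identifier names
# ---------------------------------------------------------------------------


def _encode(df: pd.DataFrame, columns: Sequence[str]) -> tuple[pd.DataFrame, dict]:
    enc = pd.DataFrame(index=df.index)
    decoders: dict[str, tuple[str, object]] = {}
    for col in columns:
        s = df[col]
        if col in schema.CATEGORICAL_DOMAINS:
            domain = list(schema.CATEGORICAL_DOMAINS[col])
            codes = pd.Categorical(s, categories=domain).codes.astype(float)
            codes[codes < 0] = np.nan
            enc[col] = codes
            decoders[col] = ("categorical", domain)
        elif col in schema.BOOLEAN_COLUMNS or s.dtype == bool or str(s.dtype) == "boolean":
            enc[col] = s.astype("Float64").to_numpy(dtype=float, na_value=np.nan)
            decoders[col] = ("boolean", None)
        else:
            enc[col] = pd.to_numeric(s).to_numpy(dtype=float, na_value=np.nan)
            decoders[col] = ("numeric", None)
    return enc, decoders


def _decode(enc: pd.DataFrame, decoders: dict) -> pd.DataFrame:
    out = pd.DataFrame(index=enc.index)
    for col, (kind, domain) in decoders.items():
        if kind == "categorical":
            codes = np.rint(enc[col].to_numpy()).astype(int)
            out[col] = pd.array(
                [domain[c] for c in codes], dtype="string"
            )
        elif kind == "boolean":
            out[col] = pd.array(enc[col].to_numpy() > 0.5, dtype="boolean")
        else:
            out[col] = enc[col].to_numpy()
    return out


def mice_impute(
    cohort: pd.DataFrame,
    config: ImputationConfig,
    columns: Sequence[str] | None = None,
    outcome: str | None = None,
) -> ImputedStack:
    """Impute missing predictor cells, returning ``m`` completed cohorts.

    ``columns`` are the variables entering the chained-equations model
    (default: every data-dictionary predictor column present in the cohort,
    plus region). ``outcome`` (and any other outcome column listed) joins the
    imputation model as a predictor but must be fully observed — outcome
    cells are never imputed.
    """
    if columns is None:
        candidates = (
            list(schema.NUMERIC_COLUMNS)
            + [c for c in schema.CATEGORICAL_DOMAINS if c not in ("laterality", "hematoma_type")]
            + [c for c in schema.BOOLEAN_COLUMNS if c not in schema.OUTCOME_COLUMNS]
        )
        columns = [c for c in candidates if c in cohort.columns]
    columns = list(columns)
    if outcome is not None and outcome not in columns:
        columns.append(outcome)
    for col in columns:
        if col in schema.OUTCOME_COLUMNS and cohort[col].isna().any():
            raise OutcomeImputationError(
                f"outcome column '{col}' has missing values; outcomes are "
                "never imputed — drop outcome-missing records upstream"
            )
    # region is design information: it joins every conditional model as
    # fully-observed indicator columns and is itself never imputed
    impute_cols = [c for c in columns if c != "region"]
    enc, decoders = _encode(cohort, impute_cols)
    if "region" in cohort.columns:
        if cohort["region"].isna().any():
            raise ImputationError("region must be observed for every record")
        for reg in schema.REGIONS[1:]:
            enc[f"region__{reg.replace('-', '_')}"] = (
                (cohort["region"] == reg).to_numpy(dtype=float)
            )
    columns = impute_cols
    all_missing = [c for c in enc.columns if enc[c].isna().all()]
    if all_missing:
        raise UnimputableVariableError(
            f"column(s) {all_missing} have no observed values in any region"
        )
    incomplete = [c for c in enc.columns if enc[c].isna().any()]
    imputed_mask = enc.isna()
    if not incomplete:
        datasets = [cohort.copy() for _ in range(config.m)]
        return ImputedStack(datasets, imputed_mask, config)

    # constant columns break the per-variable regressions; hold them aside
    work = enc.reset_index(drop=True)
    constant = [c for c in work.columns if work[c].nunique(dropna=True) <= 1]
    for c in constant:
        # a column constant where observed has only one plausible donor value
        if work[c].isna().any():
            work[c] = work[c].fillna(work[c].dropna().iloc[0])
    held = work[constant]
    work = work.drop(columns=constant)

    seeds = np.random.SeedSequence(config.seed).generate_state(config.m) % (2**31)
    datasets = []
    saved_state = np.random.get_state()
    try:
        for s in seeds:
            np.random.seed(int(s))  # MICEData draws from the global RNG
            md = MICEData(work.copy(), k_pmm=config.k_pmm)
            md.update_all(config.iterations)
            completed = md.data.copy()
            completed[held.columns] = held.to_numpy()
            completed.index = enc.index
            decoded = _decode(completed[columns], decoders)
            out = cohort.copy()
            for col in columns:
                out[col] = decoded[col].to_numpy()
            datasets.append(out)
    finally:
        np.random.set_state(saved_state)

    # observed-data immutability: imputation must not alter observed cells
    for ds in datasets:
        for col in incomplete:
            obs = ~imputed_mask[col]
            left = ds.loc[obs, col].astype(cohort[col].dtype).reset_index(drop=True)
            if not left.equals(cohort.loc[obs, col].reset_index(drop=True)):
                raise ImputationError(
                    f"observed cells of '{col}' altered during imputation"
                )
    return ImputedStack(datasets, imputed_mask, config)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    within: float  # W, mean within-imputation variance
    between: float  # B, between-imputation variance of estimates
    total: float  # T = W + (1 + 1/m) B
    df: float
    ci_low: float
    ci_high: float
    m: int


def rubin_pool(
    estimates: Sequence[float],
    variances: Sequence[float],
    dfcom: float | None = None,
) -> PooledEstimate:
    """Combine per-imputation estimates and variances with Rubin's rules.

    ``dfcom`` is the complete-data degrees of freedom; when given, the
    Barnard–Rubin small-sample adjustment is applied, otherwise the classic
    large-sample degrees of freedom are used.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise PoolingError("estimates and variances must be equal-length 1-d")
    m = len(q)
    if m < 2:
        raise PoolingError("need at least 2 imputations to pool")
    if np.any(u < 0):
        raise PoolingError("variances must be non-negative")
    qbar = float(q.mean())
    w = float(u.mean())
    b = 0.0 if np.ptp(q) == 0.0 else float(q.var(ddof=1))
    t_var = w + (1.0 + 1.0 / m) * b
    if b == 0.0 or t_var == 0.0:
        df = float("inf")
        half = Z975 * np.sqrt(t_var)
    else:
        lam = (1.0 + 1.0 / m) * b / t_var
        df_old = (m - 1) / lam**2
        if dfcom is not None and np.isfinite(dfcom):
            df_obs = (dfcom + 1.0) / (dfcom + 3.0) * dfcom * (1.0 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
        half = float(t_dist.ppf(0.975, df)) * np.sqrt(t_var)
    return PooledEstimate(
        estimate=qbar,
        within=w,
        between=b,
        total=t_var,
        df=df,
        ci_low=qbar - half,
        ci_high=qbar + half,
        m=m,
    )


def _pooled_to_ci(p: PooledEstimate) -> EstimateWithCI:
    return EstimateWithCI(p.estimate, p.ci_low, p.ci_high, float(np.sqrt(p.total)))


def pool_validation(
    stack: ImputedStack,
    spec: ModelSpec,
    n_boot: int = 2000,
    seed: int | None = None,
    row_mask: np.ndarray | None = None,
) -> ValidationResult:
    """Validate a model on every completed dataset and pool with Rubin's rules.

    Intercept and slope pool on their natural (logit-coefficient) scale; the
    C-index pools on the log-odds scale (per-imputation bootstrap variance of
    logit C) and is back-transformed; mbc — a function of predictions only —
    is averaged. ``row_mask`` restricts to a subgroup/region of the stack.
    """
    seeds = np.random.SeedSequence(seed).generate_state(stack.m) % (2**31)
    intercepts, slopes, c_logits = [], [], []
    var_a, var_b, var_c = [], [], []
    mbcs, mean_preds, cs = [], [], []
    n = events = None
    for i, ds in enumerate(stack.datasets):
        df = ds if row_mask is None else ds.loc[row_mask]
        try:
            p, _ = predict_probabilities(df, spec)
            y = df[spec.outcome].astype("boolean").to_numpy(dtype=float, na_value=np.nan)
            citl = calibration_in_the_large(p, y)
            slope = calibration_slope(p, y)
            conc = concordance(p, y, n_boot=n_boot, seed=int(seeds[i]))
        except Exception as exc:
            raise ImputationError(
                f"validation failed on imputation {i + 1}: {exc}"
            ) from exc
        if n is None:
            n, events = len(y), int(np.nansum(y))
        intercepts.append(citl.intercept.estimate)
        var_a.append(citl.intercept.se**2)
        slopes.append(slope.slope.estimate)
        var_b.append(slope.slope.se**2)
        c = np.clip(conc.c.estimate, PROB_CLIP, 1 - PROB_CLIP)
        c_logits.append(float(_logit(c)))
        var_c.append(conc.se_logit**2 if np.isfinite(conc.se_logit) else 0.0)
        cs.append(conc.c.estimate)
        mbcs.append(model_based_concordance(p))
        mean_preds.append(float(np.mean(p)))
    pa = rubin_pool(intercepts, var_a, dfcom=n - 1)
    pb = rubin_pool(slopes, var_b, dfcom=n - 2)
    pc = rubin_pool(c_logits, var_c, dfcom=n - 1)
    c_ci = EstimateWithCI(
        float(_expit(pc.estimate)),
        float(_expit(pc.ci_low)),
        float(_expit(pc.ci_high)),
        float(np.sqrt(pc.total)),
    )
    return ValidationResult(
        n=n,
        events=events,
        mean_predicted=float(np.mean(mean_preds)),
        mean_observed=events / n,
        intercept=_pooled_to_ci(pa),
        slope=_pooled_to_ci(pb),
        c_index=c_ci,
        mbc=float(np.mean(mbcs)),
    )
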