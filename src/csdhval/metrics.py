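"""Performance statistics for external validation of risk models.

Given predicted probabilities ``p`` (with linear predictor ``lp = logit p``)
and observed binary outcomes ``y``:

* **Calibration-in-the-large** — mean predicted vs. observed risk, plus the
  calibration intercept ``a`` from the offset logistic model
  ``logit Pr(y=1) = a + lp`` (slope fixed at 1). ``a > 0`` means predictions
  run too low, ``a < 0`` too high.
* **Calibration slope** — ``b`` from ``logit Pr(y=1) = alpha + b*lp``;
  ``b < 1`` flags overfitted (too extreme) predictions, ``b > 1`` underfitted.
* **Concordance index** — probability that a random event patient received a
  higher prediction than a random non-event patient, ties credited 0.5;
  computed from mid-ranks (equivalent to pair counting), CI by seeded
  nonparametric bootstrap.
* **Model-based concordance (mbc)** — the C-index expected if the predictions
  were exactly the true risks, a pure function of the predicted-risk
  distribution (the case-mix); comparing C with mbc separates coefficient
  validity from case-mix heterogeneity.
* **Calibration curves** — equal-count risk-decile points or a lowess
  smoother, exported as data for plotting.

Logistic fits use maximum likelihood (statsmodels GLM/IRLS) with Wald 95%
confidence intervals from the information matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit as _expit
from scipy.special import logit as _logit
from scipy.stats import norm, rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model_registry import PROB_CLIP

Z975 = float(norm.ppf(0.975))

#: default bootstrap replicates for the C-index confidence interval
DEFAULT_BOOTSTRAP = 2000

#: coefficients larger than this in absolute value flag (quasi-)separation
_MAX_ABS_COEF = 50.0


class EstimationError(RuntimeError):
    """A statistic cannot be estimated on these data (degenerate outcome
    vector, separation, non-convergence)."""


class DegeneratePredictorError(EstimationError):
    """The linear predictor is constant; the calibration slope is undefined."""


@dataclass(frozen=True)
class EstimateWithCI:
    estimate: float
    ci_low: float
    ci_high: float
    se: float = float("nan")

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                f"{self.estimate}"
            )


@dataclass(frozen=True)
class ValidationResult:
    """One table row of validation performance for one model on one set."""

    n: int
    events: int
    mean_predicted: float
    mean_observed: float
    intercept: EstimateWithCI
    slope: EstimateWithCI
    c_index: EstimateWithCI
    mbc: float

    def __post_init__(self):
        if self.events > self.n:
            raise ValueError("events exceed n")


def _check_py(p, y) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("p and y must be equal-length 1-d arrays")
    if len(p) < 2:
        raise ValueError("need at least 2 observations")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("outcomes must be binary 0/1")
    return p, y


def _require_events_and_nonevents(y: np.ndarray) -> None:
    if y.sum() == 0:
        raise EstimationError("no events observed; statistic not estimable")
    if y.sum() == len(y):
        raise EstimationError("no non-events observed; statistic not estimable")


def _glm_logistic(y: np.ndarray, exog: np.ndarray, offset=None):
    res = sm.GLM(y, exog, family=sm.families.Binomial(), offset=offset).fit()
    if not np.all(np.isfinite(res.params)) or np.any(
        np.abs(res.params) > _MAX_ABS_COEF
    ):
        raise EstimationError(
            "logistic fit diverged (possible separation); "
            f"coefficients {res.params}"
        )
    return res


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationInTheLarge:
    mean_predicted: float
    mean_observed: float
    intercept: EstimateWithCI


def calibration_in_the_large(p, y) -> CalibrationInTheLarge:
    """Mean predicted vs. observed risk and the calibration intercept.

    The intercept is the MLE of ``a`` in ``logit Pr(y=1) = a + lp`` with the
    linear predictor entering as a fixed offset (slope constrained to 1).
    """
    p, y = _check_py(p, y)
    _require_events_and_nonevents(y)
    lp = _logit(np.clip(p, PROB_CLIP, 1 - PROB_CLIP))
    res = _glm_logistic(y, np.ones((len(y), 1)), offset=lp)
    a, se = float(res.params[0]), float(res.bse[0])
    return CalibrationInTheLarge(
        mean_predicted=float(p.mean()),
        mean_observed=float(y.mean()),
        intercept=EstimateWithCI(a, a - Z975 * se, a + Z975 * se, se),
    )


@dataclass(frozen=True)
class CalibrationSlope:
    slope: EstimateWithCI
    intercept: float  # companion intercept alpha of the slope model


def calibration_slope(p, y) -> CalibrationSlope:
    """MLE of ``b`` in ``logit Pr(y=1) = alpha + b*lp`` with Wald 95% CI."""
    p, y = _check_py(p, y)
    _require_events_and_nonevents(y)
    lp = _logit(np.clip(p, PROB_CLIP, 1 - PROB_CLIP))
    if np.ptp(lp) == 0.0:
        raise DegeneratePredictorError(
            "linear predictor is constant; calibration slope undefined"
        )
    exog = sm.add_constant(lp)
    res = _glm_logistic(y, exog)
    b, se = float(res.params[1]), float(res.bse[1])
    return CalibrationSlope(
        slope=EstimateWithCI(b, b - Z975 * se, b + Z975 * se, se),
        intercept=float(res.params[0]),
    )


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------


def c_statistic(p, y) -> float:
    """Concordance index via mid-ranks (ties credited 0.5).

    Algebraically identical to counting concordant + 0.5*tied pairs over all
    event/non-event pairs.
    """
    p, y = _check_py(p, y)
    _require_events_and_nonevents(y)
    r = rankdata(p)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((r[y == 1].mean() - (n1 + 1) / 2.0) / n0)


@dataclass(frozen=True)
class Concordance:
    c: EstimateWithCI
    se_logit: float  # bootstrap SD of logit(C), for pooling on the logit scale
    n_boot: int


def concordance(p, y, n_boot: int = DEFAULT_BOOTSTRAP, seed=None) -> Concordance:
    """C-index with a seeded nonparametric (percentile) bootstrap CI.

    ``n_boot=0`` skips the bootstrap and returns a degenerate CI at the
    point estimate.
    """
    p, y = _check_py(p, y)
    c = c_statistic(p, y)
    if n_boot == 0:
        return Concordance(
            c=EstimateWithCI(c, c, c, 0.0), se_logit=float("nan"), n_boot=0
        )
    rng = np.random.default_rng(seed)
    n = len(p)
    reps = np.empty(n_boot)
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.sum() in (0, n):  # degenerate resample carries no information
            continue
        reps[kept] = c_statistic(p[idx], yb)
        kept += 1
    if kept < max(10, n_boot // 10):
        raise EstimationError(
            "too few informative bootstrap resamples for a C-index CI"
        )
    reps = reps[:kept]
    lo, hi = np.quantile(reps, [0.025, 0.975])
    lo, hi = min(lo, c), max(hi, c)
    se_logit = float(np.std(_logit(np.clip(reps, PROB_CLIP, 1 - PROB_CLIP)), ddof=1))
    return Concordance(
        c=EstimateWithCI(c, float(lo), float(hi), float(np.std(reps, ddof=1))),
        se_logit=se_logit,
        n_boot=kept,
    )


def model_based_concordance(p) -> float:
    """Expected C-index if each prediction were the true event probability.

    Treating ``p_i`` as the true risk, over unordered pairs with
    ``p_i > p_j`` the probability of a concordant event/non-event ordering is
    ``p_i (1-p_j)`` and of a discordant one ``p_j (1-p_i)``; tied predictions
    contribute half their informative mass. Uses no outcomes, so it reflects
    only the case-mix heterogeneity of the validation sample.

    O(n log n); matches the O(n^2) pairwise definition to float precision.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("need at least 2 predicted probabilities")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    n = len(p)
    s1 = p.sum()
    s2 = (p * p).sum()
    denom = (n - 1) * s1 - (s1 * s1 - s2)  # sum over pairs of p_i+p_j-2p_ip_j
    if denom <= 0:
        return 0.5  # no informative pair mass (all p identical at 0 or 1)
    vals, counts = np.unique(np.sort(p), return_counts=True)
    if len(vals) == 1:
        return 0.5  # every pair tied
    cnt_below = np.concatenate(([0.0], np.cumsum(counts)[:-1]))
    sum_below = np.concatenate(([0.0], np.cumsum(vals * counts)[:-1]))
    num_strict = np.sum(counts * vals * (cnt_below - sum_below))
    num_ties = np.sum(vals * (1.0 - vals) * counts * (counts - 1) / 2.0)
    return float((num_strict + num_ties) / denom)


# ---------------------------------------------------------------------------
# calibration curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    method: str  # deciles | smoother
    predicted: np.ndarray  # per-point mean predicted risk / grid
    observed: np.ndarray  # per-point observed proportion / smoothed estimate
    counts: np.ndarray  # per-bin counts (deciles) or zeros (smoother)
    reduced_bins: bool = False  # fewer distinct predictions than requested bins


def calibration_curve(
    p, y, method: str = "deciles", bins: int = 10, span: float = 0.75
) -> CalibrationCurve:
    """Grouped (equal-count deciles) or smoothed observed-vs-predicted curve."""
    p, y = _check_py(p, y)
    if method == "deciles":
        if len(p) < 20:
            raise ValueError("need n >= 20 for grouped calibration")
        n_distinct = len(np.unique(p))
        reduced = n_distinct < bins
        eff_bins = min(bins, n_distinct)
        order = np.argsort(p, kind="stable")
        groups = np.array_split(order, eff_bins)
        pred = np.array([p[g].mean() for g in groups])
        obs = np.array([y[g].mean() for g in groups])
        counts = np.array([len(g) for g in groups])
        return CalibrationCurve("deciles", pred, obs, counts, reduced)
    if method == "smoother":
        sm_xy = lowess(y, p, frac=span, return_sorted=True)
        return CalibrationCurve(
            "smoother",
            sm_xy[:, 0],
            np.clip(sm_xy[:, 1], 0.0, 1.0),
            np.zeros(len(sm_xy), dtype=int),
        )
    raise ValueError(f"unknown calibration-curve method {method!r}")


# ---------------------------------------------------------------------------
# one-call validation
# ---------------------------------------------------------------------------


def validate_predictions(
    p, y, n_boot: int = DEFAULT_BOOTSTRAP, seed=None
) -> ValidationResult:
    """All validation statistics for one (predictions, outcomes) pair."""
    p, y = _check_py(p, y)
    citl = calibration_in_the_large(p, y)
    slope = calibration_slope(p, y)
    conc = concordance(p, y, n_boot=n_boot, seed=seed)
    return ValidationResult(
        n=len(y),
        events=int(y.sum()),
        mean_predicted=citl.mean_predicted,
        mean_observed=citl.mean_observed,
        intercept=citl.intercept,
        slope=slope.slope,
        c_index=conc.c,
        mbc=model_based_concordance(p),
    )
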