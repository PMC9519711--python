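"""Data-driven engine for published prognostic risk scores and nomograms.

A published model is represented entirely as data (:class:`ModelSpec`):
predictor categorization rules with per-category points, and a risk map that
converts a total score (integer score table) or total nomogram points
(piecewise-linear curve) into a predicted probability. The engine evaluates a
model on patient records and returns predicted probabilities together with
their logits (linear predictors), which the calibration metrics consume as
offsets.

Model-definition files are YAML; see ``data/models/`` for the shipped
examples and the README for the schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import schema

#: probabilities are clipped into [PROB_CLIP, 1 - PROB_CLIP] before the logit
#: so degenerate risk maps still yield finite linear predictors
PROB_CLIP = 1e-6

VALID_OUTCOMES = set(schema.OUTCOME_COLUMNS)


class ModelSpecError(ValueError):
    """A model-definition file violates the schema or an invariant."""


class MissingPredictorError(ValueError):
    """A record lacks a predictor the model needs; caller decides whether to
    exclude the record (complete-case) or impute."""


class RiskMapDomainError(ValueError):
    """A total score/points value falls outside the risk map's domain."""


def logit(p: float | np.ndarray) -> float | np.ndarray:
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return np.log(p / (1.0 - p))


def expit(x: float | np.ndarray) -> float | np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# predictor rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdCategory:
    """Half-open/closed numeric interval with explicit boundary inclusion.

    ``lo is None`` means unbounded below, ``hi is None`` unbounded above.
    """

    label: str
    points: float
    lo: float | None = None
    lo_inclusive: bool = True
    hi: float | None = None
    hi_inclusive: bool = False

    def contains(self, x: float) -> bool:
        if self.lo is not None:
            if x < self.lo or (x == self.lo and not self.lo_inclusive):
                return False
        if self.hi is not None:
            if x > self.hi or (x == self.hi and not self.hi_inclusive):
                return False
        return True


@dataclass(frozen=True)
class NamedCategory:
    label: str
    points: float
    values: tuple[Any, ...] = ()


@dataclass(frozen=True)
class PredictorRule:
    """How one patient field contributes points to a model.

    kind:
      * ``threshold_category`` — numeric field cut into intervals, each with
        its own points; intervals must tile the real line with explicit
        boundary ownership (``< 80`` vs ``>= 80`` are distinct encodings).
      * ``named_category`` — categorical/boolean field; listed value groups
        must partition the field's domain.
      * ``continuous_points`` — continuous nomogram axis; points are read by
        piecewise-linear interpolation between tabulated anchors, clamped at
        the extremes (manual nomogram reading).
    """

    field: str
    kind: str
    categories: tuple[ThresholdCategory | NamedCategory, ...] = ()
    anchors: tuple[tuple[float, float], ...] = ()  # (value, points), sorted

    def points_for(self, values: np.ndarray) -> np.ndarray:
        """Vectorized per-record points for this rule.

        Raises :class:`MissingPredictorError` if any value is missing.
        """
        missing = pd.isna(values)
        if np.any(missing):
            raise MissingPredictorError(
                f"predictor '{self.field}' missing for {int(np.sum(missing))} record(s)"
            )
        if self.kind == "threshold_category":
            x = np.asarray(values, dtype=float)
            out = np.full(x.shape, np.nan)
            for cat in self.categories:
                mask = np.ones(x.shape, dtype=bool)
                if cat.lo is not None:
                    mask &= (x > cat.lo) | ((x == cat.lo) & cat.lo_inclusive)
                if cat.hi is not None:
                    mask &= (x < cat.hi) | ((x == cat.hi) & cat.hi_inclusive)
                out[mask] = cat.points
            if np.any(np.isnan(out)):
                bad = np.asarray(values)[np.isnan(out)][0]
                raise RiskMapDomainError(
                    f"value {bad!r} of '{self.field}' not covered by any category"
                )
            return out
        if self.kind == "named_category":
            mapping = {v: c.points for c in self.categories for v in c.values}
            out = np.empty(len(values), dtype=float)
            for i, v in enumerate(np.asarray(values, dtype=object)):
                if isinstance(v, (bool, np.bool_)):
                    v = bool(v)
                try:
                    out[i] = mapping[v]
                except KeyError:
                    raise RiskMapDomainError(
                        f"value {v!r} of '{self.field}' not covered by any category"
                    ) from None
            return out
        if self.kind == "continuous_points":
            x = np.asarray(values, dtype=float)
            xs = np.array([a[0] for a in self.anchors])
            ys = np.array([a[1] for a in self.anchors])
            return np.interp(x, xs, ys)  # np.interp clamps at the extremes
        raise ModelSpecError(f"unknown predictor kind {self.kind!r}")


# ---------------------------------------------------------------------------
# risk maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskMap:
    """Mapping from total score/points to predicted probability.

    ``score_table`` is an exact integer lookup; ``nomogram_curve`` is monotone
    piecewise-linear interpolation over (total points, probability) knots,
    clamped outside the tabulated range.
    """

    kind: str  # score_table | nomogram_curve
    entries: tuple[tuple[float, float], ...]  # (score/points, probability)

    def probability_for(self, total: np.ndarray) -> np.ndarray:
        total = np.atleast_1d(np.asarray(total, dtype=float))
        if self.kind == "score_table":
            table = {s: p for s, p in self.entries}
            out = np.empty(total.shape, dtype=float)
            for i, s in enumerate(total):
                try:
                    out[i] = table[float(s)]
                except KeyError:
                    raise RiskMapDomainError(
                        f"score {s!r} not in the model's score table"
                    ) from None
            return out
        xs = np.array([e[0] for e in self.entries])
        ys = np.array([e[1] for e in self.entries])
        return np.interp(total, xs, ys)


@dataclass(frozen=True)
class TargetPopulation:
    """Eligibility rule of the development study, e.g. age > 65."""

    field: str
    op: str  # one of >, >=, <, <=, ==
    value: float

    _OPS = {
        ">": np.greater,
        ">=": np.greater_equal,
        "<": np.less,
        "<=": np.less_equal,
        "==": np.equal,
    }

    @property
    def label(self) -> str:
        return f"{self.field}{self.op}{self.value:g}"

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        vals = df[self.field]
        ok = ~pd.isna(vals)
        out = np.zeros(len(df), dtype=bool)
        out[ok.to_numpy()] = self._OPS[self.op](
            np.asarray(vals[ok], dtype=float), self.value
        )
        return out


@dataclass(frozen=True)
class ModelSpec:
    """One published prognostic model, fully as data."""

    name: str
    outcome: str
    predictors: tuple[PredictorRule, ...]
    risk_map: RiskMap
    target_population: TargetPopulation | None = None
    source: str = ""

    @property
    def required_fields(self) -> tuple[str, ...]:
        return tuple(r.field for r in self.predictors)


@dataclass(frozen=True)
class RiskPrediction:
    """Predicted probability and its logit for one patient under one model."""

    probability: float
    linear_predictor: float
    model: str
    patient: str = ""


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _as_frame(record: Mapping[str, Any] | pd.Series | pd.DataFrame) -> pd.DataFrame:
    if isinstance(record, pd.DataFrame):
        return record
    if isinstance(record, pd.Series):
        return record.to_frame().T
    return pd.DataFrame([record])


def total_points(records: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Sum of per-predictor points for every record (vectorized)."""
    df = _as_frame(records)
    total = np.zeros(len(df), dtype=float)
    for rule in spec.predictors:
        if rule.field not in df.columns:
            raise MissingPredictorError(f"predictor column '{rule.field}' absent")
        total += rule.points_for(df[rule.field].to_numpy())
    return total


def evaluate_score(record: Mapping[str, Any] | pd.Series, spec: ModelSpec) -> int:
    """Integer total score of a score-table model for one record."""
    s = total_points(_as_frame(record), spec)[0]
    if abs(s - round(s)) > 1e-9:
        raise ModelSpecError(f"non-integer total score {s} for model '{spec.name}'")
    return int(round(s))


def evaluate_nomogram_points(
    record: Mapping[str, Any] | pd.Series, spec: ModelSpec
) -> float:
    """Real-valued total nomogram points for one record."""
    return float(total_points(_as_frame(record), spec)[0])


def predict_probabilities(
    records: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted probability and linear predictor per record.

    Probabilities are clipped into ``[PROB_CLIP, 1-PROB_CLIP]`` before the
    logit; the returned probabilities are the clipped values so that
    ``lp == logit(p)`` holds exactly.
    """
    totals = total_points(records, spec)
    p = np.clip(spec.risk_map.probability_for(totals), PROB_CLIP, 1.0 - PROB_CLIP)
    return p, np.log(p / (1.0 - p))


def predict_probability(
    record: Mapping[str, Any] | pd.Series, spec: ModelSpec
) -> RiskPrediction:
    """Single-record prediction with provenance."""
    df = _as_frame(record)
    p, lp = predict_probabilities(df, spec)
    patient = ""
    if "patient_id" in df.columns and not pd.isna(df["patient_id"].iloc[0]):
        patient = str(df["patient_id"].iloc[0])
    return RiskPrediction(
        probability=float(p[0]),
        linear_predictor=float(lp[0]),
        model=spec.name,
        patient=patient,
    )


# ---------------------------------------------------------------------------
# loading & validation
# ---------------------------------------------------------------------------


def _require(mapping: Mapping[str, Any], key: str, ctx: str) -> Any:
    if key not in mapping:
        raise ModelSpecError(f"{ctx}: missing required field '{key}'")
    return mapping[key]


def _build_threshold_rule(fieldname: str, cats: Sequence[Mapping]) -> PredictorRule:
    built = []
    for c in cats:
        built.append(
            ThresholdCategory(
                label=str(c.get("label", "")),
                points=float(_require(c, "points", f"predictor '{fieldname}'")),
                lo=None if c.get("min") is None else float(c["min"]),
                lo_inclusive=bool(c.get("min_inclusive", True)),
                hi=None if c.get("max") is None else float(c["max"]),
                hi_inclusive=bool(c.get("max_inclusive", False)),
            )
        )
    # exhaustive & mutually exclusive over the reals: sorted intervals must
    # tile the line, each boundary owned by exactly one side
    def lo_key(cat: ThresholdCategory) -> float:
        return -math.inf if cat.lo is None else cat.lo

    ordered = sorted(built, key=lo_key)
    if ordered[0].lo is not None:
        raise ModelSpecError(
            f"predictor '{fieldname}': lowest category must be unbounded below"
        )
    if ordered[-1].hi is not None:
        raise ModelSpecError(
            f"predictor '{fieldname}': highest category must be unbounded above"
        )
    for a, b in zip(ordered, ordered[1:]):
        if a.hi is None or b.lo is None or a.hi != b.lo:
            raise ModelSpecError(
                f"predictor '{fieldname}': categories '{a.label}' and '{b.label}' "
                "do not share a boundary (gap or overlap)"
            )
        if a.hi_inclusive == b.lo_inclusive:
            side = "both include" if a.hi_inclusive else "neither includes"
            raise ModelSpecError(
                f"predictor '{fieldname}': {side} the boundary {a.hi:g} "
                f"(categories '{a.label}', '{b.label}')"
            )
    return PredictorRule(
        field=fieldname, kind="threshold_category", categories=tuple(ordered)
    )


def _build_named_rule(fieldname: str, cats: Sequence[Mapping]) -> PredictorRule:
    built = []
    for c in cats:
        values = _require(c, "values", f"predictor '{fieldname}'")
        built.append(
            NamedCategory(
                label=str(c.get("label", "")),
                points=float(_require(c, "points", f"predictor '{fieldname}'")),
                values=tuple(values),
            )
        )
    seen: set = set()
    for cat in built:
        for v in cat.values:
            if v in seen:
                raise ModelSpecError(
                    f"predictor '{fieldname}': value {v!r} in more than one category"
                )
            seen.add(v)
    domain = schema.FIELD_DOMAINS.get(fieldname)
    if domain is not None:
        uncovered = [v for v in domain if v not in seen]
        if uncovered:
            raise ModelSpecError(
                f"predictor '{fieldname}': categories not exhaustive; "
                f"uncovered values {uncovered!r}"
            )
    return PredictorRule(field=fieldname, kind="named_category", categories=tuple(built))


def _build_continuous_rule(fieldname: str, anchors: Sequence[Mapping]) -> PredictorRule:
    pairs = []
    for a in anchors:
        pairs.append(
            (
                float(_require(a, "value", f"predictor '{fieldname}'")),
                float(_require(a, "points", f"predictor '{fieldname}'")),
            )
        )
    pairs.sort()
    if len(pairs) < 2:
        raise ModelSpecError(f"predictor '{fieldname}': need >= 2 anchors")
    xs = [p[0] for p in pairs]
    if len(set(xs)) != len(xs):
        raise ModelSpecError(f"predictor '{fieldname}': duplicate anchor values")
    return PredictorRule(
        field=fieldname, kind="continuous_points", anchors=tuple(pairs)
    )


def _build_risk_map(raw: Mapping[str, Any]) -> RiskMap:
    kind = _require(raw, "kind", "risk_map")
    if kind not in ("score_table", "nomogram_curve"):
        raise ModelSpecError(f"risk_map: unknown kind {kind!r}")
    key = "table" if kind == "score_table" else "curve"
    rows = _require(raw, key, "risk_map")
    entries = []
    for r in rows:
        x = float(_require(r, "score" if kind == "score_table" else "points", "risk_map"))
        p = float(_require(r, "probability", "risk_map"))
        if not (0.0 < p < 1.0):
            raise ModelSpecError(
                f"risk_map: probability {p} outside the open interval (0, 1)"
            )
        entries.append((x, p))
    entries.sort()
    xs = [e[0] for e in entries]
    ps = [e[1] for e in entries]
    if kind == "score_table":
        for x in xs:
            if abs(x - round(x)) > 1e-9:
                raise ModelSpecError(f"risk_map: non-integer score {x} in score table")
        if len(set(xs)) != len(xs):
            raise ModelSpecError("risk_map: duplicate score entries")
    else:
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ModelSpecError("risk_map: nomogram points must be strictly increasing")
    if any(b < a for a, b in zip(ps, ps[1:])):
        raise ModelSpecError(
            "risk_map: probabilities must be non-decreasing in score/points"
        )
    return RiskMap(kind=kind, entries=tuple(entries))


def build_model_spec(raw: Mapping[str, Any]) -> ModelSpec:
    """Validate a parsed model definition and build the ModelSpec."""
    name = str(_require(raw, "name", "model"))
    outcome = str(_require(raw, "outcome", f"model '{name}'"))
    if outcome not in VALID_OUTCOMES:
        raise ModelSpecError(
            f"model '{name}': outcome {outcome!r} not one of {sorted(VALID_OUTCOMES)}"
        )
    rules = []
    for p in _require(raw, "predictors", f"model '{name}'"):
        fieldname = str(_require(p, "field", f"model '{name}' predictor"))
        kind = str(_require(p, "kind", f"predictor '{fieldname}'"))
        if kind == "threshold_category":
            rules.append(
                _build_threshold_rule(
                    fieldname, _require(p, "categories", f"predictor '{fieldname}'")
                )
            )
        elif kind == "named_category":
            rules.append(
                _build_named_rule(
                    fieldname, _require(p, "categories", f"predictor '{fieldname}'")
                )
            )
        elif kind == "continuous_points":
            rules.append(
                _build_continuous_rule(
                    fieldname, _require(p, "anchors", f"predictor '{fieldname}'")
                )
            )
        else:
            raise ModelSpecError(f"predictor '{fieldname}': unknown kind {kind!r}")
    risk_map = _build_risk_map(_require(raw, "risk_map", f"model '{name}'"))
    if risk_map.kind == "score_table":
        # score-table models must produce integer totals
        for rule in rules:
            if rule.kind == "continuous_points":
                raise ModelSpecError(
                    f"model '{name}': continuous_points predictor "
                    f"'{rule.field}' incompatible with a score_table risk map"
                )
            for cat in rule.categories:
                if abs(cat.points - round(cat.points)) > 1e-9:
                    raise ModelSpecError(
                        f"model '{name}': non-integer points {cat.points} on "
                        f"'{rule.field}' with a score_table risk map"
                    )
    tp = None
    if raw.get("target_population") is not None:
        t = raw["target_population"]
        tp = TargetPopulation(
            field=str(_require(t, "field", f"model '{name}' target_population")),
            op=str(_require(t, "op", f"model '{name}' target_population")),
            value=float(_require(t, "value", f"model '{name}' target_population")),
        )
        if tp.op not in TargetPopulation._OPS:
            raise ModelSpecError(
                f"model '{name}': unknown target_population op {tp.op!r}"
            )
    return ModelSpec(
        name=name,
        outcome=outcome,
        predictors=tuple(rules),
        risk_map=risk_map,
        target_population=tp,
        source=str(raw.get("source", "")),
    )


def load_model_spec(path) -> ModelSpec:
    """Load and validate a model definition from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:  # pragma: no cover - parser detail
            raise ModelSpecError(f"{path}: cannot parse YAML: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ModelSpecError(f"{path}: model definition must be a mapping")
    try:
        return build_model_spec(raw)
    except ModelSpecError as exc:
        raise ModelSpecError(f"{path}: {exc}") from None


def shipped_model_dir():
    """Directory of the model-definition files distributed with the package."""
    from importlib.resources import files

    return files("csdhval").joinpath("data/models")


def load_shipped_models() -> dict[str, ModelSpec]:
    """All model definitions distributed with the package, keyed by name."""
    out = {}
    for entry in sorted(shipped_model_dir().iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".yaml"):
            spec = load_model_spec(str(entry))
            out[spec.name] = spec
    return out
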