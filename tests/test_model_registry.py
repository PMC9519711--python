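"""Score/nomogram engine: loading, validation, evaluation, invariants."""

import copy
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csdhval.model_registry import (
    PROB_CLIP,
    MissingPredictorError,
    ModelSpecError,
    RiskMapDomainError,
    build_model_spec,
    evaluate_nomogram_points,
    evaluate_score,
    expit,
    load_model_spec,
    load_shipped_models,
    logit,
    predict_probabilities,
    predict_probability,
)

from conftest import toy_nomogram_raw, toy_score_raw


@pytest.fixture(scope="module")
def shipped():
    return load_shipped_models()


class TestLoading:
    def test_shipped_models_load_and_validate(self, shipped):
        assert set(shipped) == {"alford_she", "jack", "andersen_a", "andersen_b"}
        alford = shipped["alford_she"]
        assert alford.outcome == "mortality_30d"
        assert len(alford.predictors) == 3
        assert alford.target_population.field == "age"
        assert alford.target_population.op == ">"
        assert alford.target_population.value == 65
        assert shipped["jack"].outcome == "recurrence_2m"
        assert shipped["andersen_a"].outcome == "recurrence_3m"
        assert shipped["andersen_b"].risk_map.kind == "nomogram_curve"

    def test_load_from_file(self, tmp_path):
        import yaml

        path = tmp_path / "toy.yaml"
        path.write_text(yaml.safe_dump(toy_score_raw()))
        spec = load_model_spec(path)
        assert spec.name == "toy_score"
        assert spec.required_fields == ("age", "gcs_category", "volume_ml")

    def test_out_of_range_probability_rejected(self):
        raw = toy_score_raw()
        raw["risk_map"]["table"][2]["probability"] = 1.2
        with pytest.raises(ModelSpecError, match="probability"):
            build_model_spec(raw)

    def test_uncovered_boundary_rejected(self):
        # {<80, >80} leaves exactly 80 uncovered
        raw = toy_score_raw()
        raw["predictors"][0]["categories"][1]["min_inclusive"] = False
        with pytest.raises(ModelSpecError, match="boundary"):
            build_model_spec(raw)

    def test_overlapping_boundary_rejected(self):
        # {<=80, >=80} assigns 80 to both categories
        raw = toy_score_raw()
        raw["predictors"][0]["categories"][0]["max_inclusive"] = True
        with pytest.raises(ModelSpecError, match="boundary"):
            build_model_spec(raw)

    def test_non_exhaustive_named_categories_rejected(self):
        raw = toy_score_raw()
        del raw["predictors"][1]["categories"][1]  # drop GCS 5-12
        with pytest.raises(ModelSpecError, match="exhaustive"):
            build_model_spec(raw)

    def test_non_monotone_risk_map_rejected(self):
        raw = toy_score_raw()
        raw["risk_map"]["table"][3]["probability"] = 0.01  # dips below score 2
        with pytest.raises(ModelSpecError, match="non-decreasing"):
            build_model_spec(raw)

    def test_missing_schema_field_names_the_field(self):
        raw = toy_score_raw()
        del raw["risk_map"]
        with pytest.raises(ModelSpecError, match="risk_map"):
            build_model_spec(raw)


class TestScoreEvaluation:
    def test_all_reference_categories_score_zero(self, toy_score_spec):
        rec = {"age": 70.0, "gcs_category": "13-15", "volume_ml": 40.0}
        assert evaluate_score(rec, toy_score_spec) == 0

    def test_age_80_boundary_differs_between_models(self, shipped):
        """Age 80 is the *upper* category for the SHE score (< 80 / >= 80)
        but the *lower* one for the Jack score (<= 80 / > 80)."""
        she_rec = {"age": 80.0, "gcs_category": "13-15", "volume_ml": 40.0}
        jack_rec = {"age": 80.0, "volume_ml": 100.0, "septations": False}
        assert evaluate_score(she_rec, shipped["alford_she"]) == 1
        assert evaluate_score(jack_rec, shipped["jack"]) == 0
        # age 85 lands in the upper category for both encodings
        she_rec["age"] = jack_rec["age"] = 85.0
        assert evaluate_score(she_rec, shipped["alford_she"]) == 1
        assert evaluate_score(jack_rec, shipped["jack"]) == 1

    def test_score_matches_exhaustive_hand_summed_table(self, toy_score_spec):
        """Every category combination equals the brute-force point sum."""
        age_reps = {0: 70.0, 1: 85.0}
        gcs_reps = {0: "3-4", 1: "5-12", 2: "13-15"}
        vol_reps = {0: 30.0, 1: 90.0}
        pts_age, pts_gcs, pts_vol = (0, 1), (2, 1, 0), (0, 1)
        for ia, ig, iv in itertools.product(range(2), range(3), range(2)):
            rec = {
                "age": age_reps[ia],
                "gcs_category": gcs_reps[ig],
                "volume_ml": vol_reps[iv],
            }
            expected = pts_age[ia] + pts_gcs[ig] + pts_vol[iv]
            assert evaluate_score(rec, toy_score_spec) == expected

    def test_missing_predictor_raises(self, toy_score_spec):
        rec = {"age": 70.0, "gcs_category": None, "volume_ml": 40.0}
        with pytest.raises(MissingPredictorError, match="gcs_category"):
            evaluate_score(rec, toy_score_spec)


class TestNomogramEvaluation:
    def test_points_at_anchor_are_exact(self, toy_nomogram_spec):
        rec = {"volume_ml": 100.0, "hypertension": False}
        assert evaluate_nomogram_points(rec, toy_nomogram_spec) == 40.0

    def test_midpoint_interpolates_linearly(self, toy_nomogram_spec):
        rec = {"volume_ml": 150.0, "hypertension": False}
        assert evaluate_nomogram_points(rec, toy_nomogram_spec) == pytest.approx(
            (40.0 + 60.0) / 2
        )

    def test_clamped_beyond_largest_anchor(self, toy_nomogram_spec):
        rec = {"volume_ml": 500.0, "hypertension": True}
        assert evaluate_nomogram_points(rec, toy_nomogram_spec) == 60.0 + 10.0

    def test_matches_reference_interpolation(self, toy_nomogram_spec):
        from scipy.interpolate import interp1d

        xs = np.array([0.0, 100.0, 200.0])
        ys = np.array([0.0, 40.0, 60.0])
        ref = interp1d(xs, ys, bounds_error=False, fill_value=(0.0, 60.0))
        for v in np.linspace(1.0, 400.0, 37):
            rec = {"volume_ml": min(v, 400.0), "hypertension": False}
            expected = float(ref(np.clip(v, 0, 200)))
            assert evaluate_nomogram_points(rec, toy_nomogram_spec) == pytest.approx(
                expected, abs=1e-12
            )


class TestPrediction:
    def test_score_table_lookup(self, toy_score_spec):
        rec = {"age": 70.0, "gcs_category": "5-12", "volume_ml": 40.0}  # S=1
        pred = predict_probability(rec, toy_score_spec)
        assert pred.probability == pytest.approx(0.08)
        assert pred.linear_predictor == pytest.approx(math.log(0.08 / 0.92))

    def test_constant_risk_map_gives_lp_zero(self):
        raw = toy_score_raw()
        for row in raw["risk_map"]["table"]:
            row["probability"] = 0.5
        spec = build_model_spec(raw)
        for gcs in ("3-4", "5-12", "13-15"):
            pred = predict_probability(
                {"age": 85.0, "gcs_category": gcs, "volume_ml": 90.0}, spec
            )
            assert pred.linear_predictor == 0.0

    def test_extreme_probability_clipped_before_logit(self):
        raw = toy_score_raw()
        raw["risk_map"]["table"][0]["probability"] = 1e-9
        spec = build_model_spec(raw)
        pred = predict_probability(
            {"age": 70.0, "gcs_category": "13-15", "volume_ml": 40.0}, spec
        )
        assert pred.probability == PROB_CLIP
        assert pred.linear_predictor == pytest.approx(math.log(PROB_CLIP / (1 - PROB_CLIP)))

    def test_score_outside_table_is_domain_error(self, toy_score_spec):
        raw = toy_score_raw()
        raw["risk_map"]["table"] = raw["risk_map"]["table"][:3]  # scores 0..2
        spec = build_model_spec(raw)
        rec = {"age": 85.0, "gcs_category": "3-4", "volume_ml": 90.0}  # S=4
        with pytest.raises(RiskMapDomainError, match="score"):
            predict_probability(rec, spec)

    def test_prediction_is_deterministic(self, toy_nomogram_spec):
        rec = {"volume_ml": 123.456, "hypertension": True}
        a = predict_probability(rec, toy_nomogram_spec)
        b = predict_probability(rec, toy_nomogram_spec)
        assert a == b


class TestInvariants:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        probs=st.lists(
            st.floats(min_value=0.01, max_value=0.99), min_size=5, max_size=5
        ),
        volumes=st.lists(
            st.floats(min_value=1.0, max_value=400.0), min_size=2, max_size=20
        ),
    )
    def test_nomogram_probability_monotone_in_volume(self, probs, volumes):
        raw = toy_nomogram_raw()
        curve_p = sorted(probs)[:3]
        for knot, pv in zip(raw["risk_map"]["curve"], curve_p):
            knot["probability"] = pv
        spec = build_model_spec(raw)
        df = pd.DataFrame(
            {"volume_ml": sorted(volumes), "hypertension": [False] * len(volumes)}
        )
        p, _ = predict_probabilities(df, spec)
        assert np.all(np.diff(p) >= -1e-15)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(p=st.floats(min_value=PROB_CLIP, max_value=1 - PROB_CLIP))
    def test_logit_roundtrip(self, p):
        assert float(expit(logit(p))) == pytest.approx(p, abs=1e-12)
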