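"""Discrimination metrics, calibration, decision curves, Model/Results API."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from habitatomics.models import (
    LearnerConfig,
    ResponseModel,
    auc_mann_whitney,
    calibration_curve,
    decision_curve,
    delong_ci,
    encode_clinical,
    evaluate_scores,
    train_fusion,
    youden_threshold,
)


def brute_force_auc(y, s):
    y = np.asarray(y, bool)
    pos, neg = np.asarray(s)[y], np.asarray(s)[~y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_concordance_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(6, 30)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.normal(size=n), 1)  # ties included
            assert abs(auc_mann_whitney(y, s) - brute_force_auc(y, s)) < 1e-12

    def test_hand_built_four_patient_sets(self):
        assert auc_mann_whitney([1, 1, 0, 0], [0.9, 0.8, 0.4, 0.1]) == 1.0
        assert auc_mann_whitney([1, 1, 0, 0], [0.9, 0.3, 0.4, 0.1]) == 0.75

    def test_delong_ci_coverage(self):
        # true AUC for N(1,1) vs N(0,1) scores is Φ(1/√2)
        true_auc = norm.cdf(1 / np.sqrt(2))
        rng = np.random.default_rng(1)
        hits = 0
        reps = 500
        for _ in range(reps):
            s = np.concatenate([rng.normal(1, 1, 100), rng.normal(0, 1, 100)])
            y = np.repeat([1, 0], 100)
            _, (lo, hi) = delong_ci(y, s)
            hits += lo <= true_auc <= hi
        assert abs(hits / reps - 0.95) < 0.03

    def test_delong_point_estimate_matches_auc(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 60)
        y[:5] = 1
        y[-5:] = 0
        s = rng.normal(size=60)
        auc, _ = delong_ci(y, s)
        assert abs(auc - auc_mann_whitney(y, s)) < 1e-12


class TestEvaluation:
    def test_perfect_classifier(self):
        y = [1, 1, 1, 0, 0, 0]
        s = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        rep = evaluate_scores(y, s, threshold=0.5)
        assert rep.auc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.confusion.sum() == 6

    def test_single_class_flagged(self):
        rep = evaluate_scores([1, 1, 1], [0.2, 0.5, 0.9], threshold=0.5)
        assert np.isnan(rep.auc)
        assert "single-class" in rep.note

    def test_youden_threshold_separates(self):
        y = np.repeat([0, 1], 50)
        s = np.concatenate([np.linspace(0, 0.45, 50), np.linspace(0.55, 1, 50)])
        t = youden_threshold(y, s)
        assert 0.45 < t <= 0.56


class TestCalibration:
    def test_well_calibrated_slope_near_one(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.05, 0.95, 2000)
        y = (rng.random(2000) < p).astype(int)
        _, intercept, slope = calibration_curve(p, y, n_bins=10)
        assert 0.9 < slope < 1.1
        assert abs(intercept) < 0.15

    def test_constant_prediction_single_bin(self):
        p = np.full(100, 0.5)
        y = np.tile([0, 1], 50)
        points, _, _ = calibration_curve(p, y, n_bins=10)
        assert len(points) == 1
        assert points.iloc[0]["mean_predicted"] == 0.5
        assert points.iloc[0]["observed_rate"] == 0.5

    def test_overconfident_slope_below_one(self):
        rng = np.random.default_rng(4)
        p_true = rng.uniform(0.1, 0.9, 3000)
        y = (rng.random(3000) < p_true).astype(int)
        logit = np.log(p_true / (1 - p_true))
        p_over = 1 / (1 + np.exp(-2 * logit))  # doubled logits
        _, _, slope = calibration_curve(p_over, y, n_bins=10)
        assert slope < 1.0

    def test_bin_count_precondition(self):
        with pytest.raises(ValueError):
            calibration_curve(np.linspace(0, 1, 10), np.zeros(10), n_bins=9)


class TestDecisionCurve:
    def test_treat_all_zero_at_prevalence(self):
        y = np.repeat([1, 0], [40, 60])
        p = np.random.default_rng(0).random(100)
        df = decision_curve(p, y, thresholds=[0.4])
        assert df["treat_all"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert (df["treat_none"] == 0).all()

    def test_perfect_classifier_nb_equals_prevalence(self):
        y = np.repeat([1, 0], [30, 70])
        p = np.where(y == 1, 0.99, 0.01)
        df = decision_curve(p, y, thresholds=np.linspace(0.05, 0.95, 10))
        np.testing.assert_allclose(df["model"], 0.30, atol=1e-12)

    def test_random_scores_bounded_by_best_default(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 4000)
        p = rng.random(4000)
        df = decision_curve(p, y)
        bound = np.maximum(df["treat_all"], 0.0)
        assert (df["model"] <= bound + 0.03).all()

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], thresholds=[0.0])


def _toy_cohort(n=120, seed=0, signal=1.5):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    x = pd.DataFrame(
        rng.normal(size=(n, 6)), columns=[f"r{i}" for i in range(6)]
    )
    x["r0"] += signal * y
    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "cT_stage": rng.choice(["cT1", "cT2", "cT3", "cT4"], n),
            "ER": rng.choice(["pos", "neg"], n),
            "HER2": rng.choice(["pos", "neg"], n),
        }
    )
    return x, y, clinical


class TestResponseModel:
    def test_fit_evaluate_roundtrip(self):
        x, y, _ = _toy_cohort()
        res = ResponseModel(x, y, model_id="preSHR").fit(cv_folds=5)
        rep = res.evaluate(x, y)
        assert rep.auc > 0.7
        assert rep.confusion.sum() == len(y)
        summary = res.summary()
        assert summary.loc["model", "value"] == "preSHR"

    def test_determinism_and_frozen_application(self):
        x, y, _ = _toy_cohort(seed=1)
        r1 = ResponseModel(x, y, config=LearnerConfig(seed=7)).fit(cv_folds=0)
        r2 = ResponseModel(x, y, config=LearnerConfig(seed=7)).fit(cv_folds=0)
        np.testing.assert_array_equal(r1.train_scores, r2.train_scores)
        # applying the frozen bundle to the training table is bit-identical
        np.testing.assert_array_equal(r1.predict(x), r1.train_scores)

    def test_null_labels_cv_auc_near_half(self):
        aucs = []
        for s in range(3):
            x, y, _ = _toy_cohort(seed=10 + s, signal=0.0)
            res = ResponseModel(x, y, config=LearnerConfig(seed=s)).fit(cv_folds=5)
            aucs.append(res.cv_auc)
        assert 0.4 < np.mean(aucs) < 0.6

    def test_single_class_rejected(self):
        x, _, _ = _toy_cohort()
        with pytest.raises(ValueError):
            ResponseModel(x, np.ones(len(x)))

    def test_fusion_uses_clinical(self):
        x, y, clinical = _toy_cohort(seed=2, signal=0.3)
        # plant clinical-only signal
        y = (
            (clinical["cT_stage"] == "cT1").to_numpy().astype(int)
            | (np.random.default_rng(3).random(len(y)) < 0.2)
        ).astype(int)
        model = train_fusion(x.iloc[:, :3], x.iloc[:, 3:], clinical, y, model_id="ClinSHR")
        res = model.fit(cv_folds=5)
        assert any(f.startswith("clin|") for f in res.bundle.feature_list)

    def test_missing_clinical_errors_with_ids(self):
        x, y, clinical = _toy_cohort()
        clinical.loc[3, "ER"] = np.nan
        with pytest.raises(ValueError, match="P3"):
            encode_clinical(clinical)

    def test_subgroup_eval(self):
        x, y, clinical = _toy_cohort(seed=4)
        res = ResponseModel(x, y).fit(cv_folds=0)
        groups = np.where(np.arange(len(y)) % 2 == 0, "A", "B")
        out = res.subgroup_eval(x, y, groups)
        assert set(out) == {"A", "B"}
        assert np.isfinite(out["A"].auc)
        # whole cohort as a single subgroup reproduces the global evaluation
        whole = res.subgroup_eval(x, y, np.repeat("all", len(y)))["all"]
        assert whole.auc == res.evaluate(x, y).auc

    def test_bundle_roundtrip_on_disk(self, tmp_path):
        from habitatomics.models import ModelBundle

        x, y, _ = _toy_cohort(seed=6)
        res = ResponseModel(x, y, config=LearnerConfig(seed=3)).fit(cv_folds=0)
        res.bundle.save(tmp_path / "bundle")
        back = ModelBundle.load(tmp_path / "bundle")
        np.testing.assert_allclose(back.predict_proba(x), res.predict(x), atol=1e-7)
        assert back.feature_list == res.bundle.feature_list
        assert back.decision_threshold == res.bundle.decision_threshold

    def test_small_subgroup_flagged(self):
        x, y, _ = _toy_cohort()
        res = ResponseModel(x, y).fit(cv_folds=0)
        groups = np.where(np.arange(len(y)) < 5, "tiny", "rest")
        out = res.subgroup_eval(x, y, groups)
        assert "not evaluated" in out["tiny"].note
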