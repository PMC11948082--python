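"""Response-prediction models: gradient-boosted trees over selected features.

Six model flavours share one implementation: four single-timepoint models
(pre/mid × whole-tumor TR / habitat SHR feature sets) and two fused models
(Clin-SHR, Clin-TR) that concatenate pre- and mid-treatment radiomics with
one-hot clinical covariates (cT stage, ER, HER2).

The API follows the statsmodels convention: build a :class:`ResponseModel`
from data, call :meth:`~ResponseModel.fit` to obtain a
:class:`ResponseResults` carrying the frozen :class:`ModelBundle`
(feature list, standardization statistics, decision threshold) plus
cross-validated discrimination; evaluation, calibration, decision-curve and
subgroup analyses hang off the results object.  Applying a fitted bundle
never refits anything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

__all__ = [
    "LearnerConfig",
    "ModelBundle",
    "EvalReport",
    "ResponseModel",
    "ResponseResults",
    "auc_mann_whitney",
    "delong_ci",
    "youden_threshold",
    "calibration_curve",
    "decision_curve",
    "encode_clinical",
]

MODEL_IDS = ("preTR", "preSHR", "midTR", "midSHR", "ClinTR", "ClinSHR")


@dataclass
class LearnerConfig:
    """Boosted-tree hyperparameters (kept modest: n≈hundreds, p≈tens)."""

    max_depth: int = 3
    learning_rate: float = 0.1
    n_estimators: int = 200
    subsample: float = 0.8
    seed: int = 0

    def make(self):
        return XGBClassifier(
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            n_estimators=self.n_estimators,
            subsample=self.subsample,
            random_state=self.seed,
            n_jobs=1,
            eval_metric="logloss",
            tree_method="hist",
        )


class _BoosterPredictor:
    """Thin prediction-only adapter around a deserialized xgboost Booster."""

    def __init__(self, booster):
        self.booster = booster

    def predict_proba(self, x):
        import xgboost

        p1 = self.booster.predict(xgboost.DMatrix(np.asarray(x, float)))
        return np.column_stack([1.0 - p1, p1])


@dataclass
class ModelBundle:
    """A frozen, applicable classifier: learner + feature list + statistics."""

    model_id: str
    learner: object
    feature_list: list
    standardization: tuple  # (means, sds) aligned to feature_list
    decision_threshold: float
    config: LearnerConfig

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_list if f not in table.columns]
        if missing:
            raise KeyError(f"bundle features missing from table: {missing[:5]}")
        x = np.asarray(table[self.feature_list], float)
        mu, sd = self.standardization
        x = (x - mu) / sd
        return self.learner.predict_proba(x)[:, 1]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(table) >= self.decision_threshold).astype(int)

    def save(self, directory) -> None:
        """Serialize as a directory: model file + JSON manifest (feature
        list, standardization statistics, threshold, learner config)."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        booster = (
            self.learner.get_booster()
            if hasattr(self.learner, "get_booster")
            else self.learner.booster
        )
        booster.save_model(str(d / "model.ubj"))
        mu, sd = self.standardization
        manifest = {
            "model_id": self.model_id,
            "feature_list": list(self.feature_list),
            "standardization_mean": np.asarray(mu).tolist(),
            "standardization_sd": np.asarray(sd).tolist(),
            "decision_threshold": self.decision_threshold,
            "learner": {
                "max_depth": self.config.max_depth,
                "learning_rate": self.config.learning_rate,
                "n_estimators": self.config.n_estimators,
                "subsample": self.config.subsample,
                "seed": self.config.seed,
            },
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        from pathlib import Path

        import xgboost

        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        config = LearnerConfig(**manifest["learner"])
        booster = xgboost.Booster()
        booster.load_model(str(d / "model.ubj"))
        learner = _BoosterPredictor(booster)
        return cls(
            manifest["model_id"],
            learner,
            manifest["feature_list"],
            (
                np.asarray(manifest["standardization_mean"]),
                np.asarray(manifest["standardization_sd"]),
            ),
            manifest["decision_threshold"],
            config,
        )


# ---------------------------------------------------------------------------
# metrics


def auc_mann_whitney(y_true, scores) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, float)
    pos, neg = s[y], s[~y]
    if pos.size == 0 or neg.size == 0:
        return np.nan
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(s.size)
    sorted_s = s[order]
    # midranks
    i = 0
    r = np.empty(s.size)
    while i < s.size:
        j = i
        while j < s.size and sorted_s[j] == sorted_s[i]:
            j += 1
        r[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    ranks[order] = r
    return float((ranks[y].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def _midrank(x):
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def delong_ci(y_true, scores, alpha=0.05):
    """DeLong variance estimate and (1−alpha) CI for a single AUC."""
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, float)
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        return np.nan, (np.nan, np.nan)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    se = np.sqrt(max(var, 0.0))
    z = norm.ppf(1 - alpha / 2)
    return float(auc), (float(np.clip(auc - z * se, 0, 1)), float(np.clip(auc + z * se, 0, 1)))


def youden_threshold(y_true, scores) -> float:
    """Operating point maximizing sensitivity + specificity − 1."""
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, float)
    cuts = np.unique(s)
    best, best_j = 0.5, -np.inf
    for c in cuts:
        pred = s >= c
        tp = np.sum(pred & y)
        tn = np.sum(~pred & ~y)
        j = tp / max(y.sum(), 1) + tn / max((~y).sum(), 1) - 1
        if j > best_j:
            best_j, best = j, float(c)
    return best


def wilson_ci(k, n, alpha=0.05):
    if n == 0:
        return (np.nan, np.nan)
    z = norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (float(center - half), float(center + half))


@dataclass
class EvalReport:
    """Discrimination + operating-point metrics of one model on one cohort."""

    auc: float
    auc_ci: tuple
    sensitivity: float
    specificity: float
    accuracy: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    threshold: float
    n: int
    sensitivity_ci: tuple = (np.nan, np.nan)
    specificity_ci: tuple = (np.nan, np.nan)
    note: str = ""

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "n": self.n,
                "AUC": self.auc,
                "AUC_lo": self.auc_ci[0],
                "AUC_hi": self.auc_ci[1],
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy,
                "threshold": self.threshold,
            }
        )


def evaluate_scores(y_true, scores, threshold) -> EvalReport:
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, float)
    n = len(y)
    if y.all() or not y.any():
        return EvalReport(
            np.nan, (np.nan, np.nan), np.nan, np.nan, np.nan,
            np.zeros((2, 2), int), threshold, n, note="single-class evaluation set",
        )
    auc, ci = delong_ci(y, s)
    pred = s >= threshold
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return EvalReport(
        auc, ci, sens, spec, (tp + tn) / n,
        np.array([[tn, fp], [fn, tp]]), threshold, n,
        wilson_ci(tp, tp + fn), wilson_ci(tn, tn + fp),
    )


def calibration_curve(predictions, labels, n_bins=10):
    """Quantile-binned reliability points + logistic recalibration line.

    Returns (DataFrame of bin points, intercept, slope) where intercept and
    slope come from refitting ``logit(y) ~ logit(p)``.
    """
    p = np.asarray(predictions, float)
    y = np.asarray(labels).astype(int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predictions must lie in [0,1]")
    if n_bins > len(p) / 2:
        raise ValueError("n_bins too large for the sample")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:  # constant predictions collapse to one bin
        edges = np.array([edges[0] - 1e-9, edges[0] + 1e-9])
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.any():
            rows.append((p[sel].mean(), y[sel].mean(), int(sel.sum())))
    points = pd.DataFrame(rows, columns=["mean_predicted", "observed_rate", "n"])
    eps = 1e-6
    lp = np.log(np.clip(p, eps, 1 - eps) / np.clip(1 - p, eps, 1 - eps))
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
    lr.fit(lp[:, None], y)
    return points, float(lr.intercept_[0]), float(lr.coef_[0, 0])


def decision_curve(predictions, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit NB(t) = TP/n − (FP/n)·t/(1−t) for model/treat-all/none."""
    p = np.asarray(predictions, float)
    y = np.asarray(labels).astype(bool)
    n = len(y)
    prev = y.mean()
    if thresholds is None:
        thresholds = np.linspace(0.05, 0.95, 19)
    thresholds = np.asarray(thresholds, float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in (0,1)")
    rows = []
    for t in thresholds:
        pred = p >= t
        tp = np.sum(pred & y) / n
        fp = np.sum(pred & ~y) / n
        w = t / (1 - t)
        rows.append((t, tp - fp * w, prev - (1 - prev) * w, 0.0))
    return pd.DataFrame(rows, columns=["threshold", "model", "treat_all", "treat_none"])


# ---------------------------------------------------------------------------
# clinical encoding + Model / Results


CT_LEVELS = ("cT1", "cT2", "cT3", "cT4")


def encode_clinical(cohort: pd.DataFrame) -> pd.DataFrame:
    """One-hot cT stage plus ER/HER2 indicator columns; errors on missing."""
    required = ["cT_stage", "ER", "HER2"]
    missing_cols = [c for c in required if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"clinical table lacks columns {missing_cols}")
    bad = cohort[required].isna().any(axis=1)
    if bad.any():
        ids = (
            cohort.loc[bad, "patient_id"].tolist()
            if "patient_id" in cohort.columns
            else list(cohort.index[bad])
        )
        raise ValueError(f"missing clinical values for patients: {ids}")
    out = pd.DataFrame(index=cohort.index)
    for lv in CT_LEVELS:
        out[f"clin|cT|{lv}"] = (cohort["cT_stage"] == lv).astype(float)
    out["clin|ER|neg"] = (cohort["ER"] == "neg").astype(float)
    out["clin|HER2|pos"] = (cohort["HER2"] == "pos").astype(float)
    return out


class ResponseModel:
    """Boosted-tree pCR model over one feature set (plus optional clinical).

    Parameters
    ----------
    table : DataFrame, patients × selected radiomics features
        For fused models pass the concatenated pre+mid selected features.
    labels : array-like of {0,1} or {"non-pCR","pCR"}
    clinical : DataFrame, optional
        Raw covariate table with cT_stage/ER/HER2 columns; one-hot encoded
        and concatenated (the fusion models).
    model_id : one of preTR/preSHR/midTR/midSHR/ClinTR/ClinSHR
    """

    def __init__(self, table, labels, clinical=None, model_id="preSHR", config=None):
        labels = np.asarray(
            [1 if str(v) in ("1", "pCR", "True") else 0 for v in labels], int
        )
        if len(np.unique(labels)) < 2:
            raise ValueError("labels contain a single class")
        x = table.copy()
        if clinical is not None:
            clin = encode_clinical(clinical)
            clin.index = x.index
            x = pd.concat([x, clin], axis=1)
        if model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")
        self.table = x
        self.labels = labels
        self.model_id = model_id
        self.config = config or LearnerConfig()

    def fit(self, cv_folds=10) -> "ResponseResults":
        """Fit the learner; record tenfold stratified CV AUC and freeze the
        Youden operating point on training predictions."""
        x = np.asarray(self.table, float)
        y = self.labels
        mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        xs = (x - mu) / sd
        cv_folds = min(cv_folds, int(np.bincount(y).min()))
        cv_aucs = []
        if cv_folds >= 2:
            skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=self.config.seed)
            for tr, te in skf.split(xs, y):
                if len(np.unique(y[te])) < 2:
                    continue
                m = self.config.make()
                m.fit(xs[tr], y[tr])
                cv_aucs.append(auc_mann_whitney(y[te], m.predict_proba(xs[te])[:, 1]))
        learner = self.config.make()
        learner.fit(xs, y)
        train_scores = learner.predict_proba(xs)[:, 1]
        bundle = ModelBundle(
            self.model_id,
            learner,
            list(self.table.columns),
            (mu, sd),
            youden_threshold(y, train_scores),
            self.config,
        )
        return ResponseResults(self, bundle, np.array(cv_aucs), train_scores)


class ResponseResults:
    """Fit artefacts: the frozen bundle plus training/CV diagnostics."""

    def __init__(self, model, bundle, cv_aucs, train_scores):
        self.model = model
        self.bundle = bundle
        self.cv_aucs = cv_aucs
        self.train_scores = train_scores

    @property
    def cv_auc(self) -> float:
        return float(np.mean(self.cv_aucs)) if self.cv_aucs.size else np.nan

    def predict(self, table) -> np.ndarray:
        return self.bundle.predict_proba(table)

    def evaluate(self, table, labels) -> EvalReport:
        labels = np.asarray(
            [1 if str(v) in ("1", "pCR", "True") else 0 for v in labels], int
        )
        return evaluate_scores(labels, self.bundle.predict_proba(table), self.bundle.decision_threshold)

    def evaluate_train(self) -> EvalReport:
        return evaluate_scores(
            self.model.labels, self.train_scores, self.bundle.decision_threshold
        )

    def calibration(self, table, labels, n_bins=10):
        labels = np.asarray(
            [1 if str(v) in ("1", "pCR", "True") else 0 for v in labels], int
        )
        return calibration_curve(self.bundle.predict_proba(table), labels, n_bins)

    def decision_curve(self, table, labels, thresholds=None):
        labels = np.asarray(
            [1 if str(v) in ("1", "pCR", "True") else 0 for v in labels], int
        )
        return decision_curve(self.bundle.predict_proba(table), labels, thresholds)

    def subgroup_eval(self, table, labels, grouping, min_patients=10):
        """Per-subgroup EvalReport (no refitting); small or single-class
        subgroups are flagged rather than scored."""
        grouping = pd.Series(np.asarray(grouping), index=table.index)
        labels = pd.Series(
            [1 if str(v) in ("1", "pCR", "True") else 0 for v in labels], index=table.index
        )
        out = {}
        for g, idx in grouping.groupby(grouping).groups.items():
            sub_y = labels.loc[idx]
            if len(idx) < min_patients or sub_y.nunique() < 2:
                out[g] = EvalReport(
                    np.nan, (np.nan, np.nan), np.nan, np.nan, np.nan,
                    np.zeros((2, 2), int), self.bundle.decision_threshold, len(idx),
                    note="not evaluated: too small or single-class",
                )
            else:
                out[g] = self.evaluate(table.loc[idx], sub_y)
        return out

    def summary(self) -> pd.DataFrame:
        """Human-readable fit summary (statsmodels-flavoured)."""
        tr = self.evaluate_train()
        rows = {
            "model": self.bundle.model_id,
            "n_patients": len(self.model.labels),
            "n_features": len(self.bundle.feature_list),
            "cv_auc": round(self.cv_auc, 4),
            "train_auc": round(tr.auc, 4),
            "train_sensitivity": round(tr.sensitivity, 4),
            "train_specificity": round(tr.specificity, 4),
            "decision_threshold": round(self.bundle.decision_threshold, 4),
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=["value"])


def train_fusion(pre_table, mid_table, clinical, labels, model_id="ClinSHR", config=None):
    """Convenience constructor for the fused models: concatenate selected
    pre- and mid-treatment features (column-prefixed) plus clinical dummies."""
    pre = pre_table.add_prefix("pre::")
    mid = mid_table.add_prefix("mid::")
    mid.index = pre.index
    table = pd.concat([pre, mid], axis=1)
    return ResponseModel(table, labels, clinical=clinical, model_id=model_id, config=config)
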