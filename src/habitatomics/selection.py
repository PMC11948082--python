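"""Staged feature-selection cascade.

Order is fixed: reliability (ICC) → variance/redundancy pruning → univariate
association (Mann-Whitney U) → sparse selection (L1-penalized logistic
regression).  Feature counts are non-increasing along the cascade and every
dropped feature keeps a recorded reason and statistic.

The reliability stage uses ICC(2,1): two-way random effects, absolute
agreement, single measurement,

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),

with MSR/MSC/MSE the patient/reader/error mean squares of the two-way ANOVA
on an n patients × k measurements table.  The univariate stage deliberately
applies no multiplicity correction (thresholding raw p < 0.05 is a known
liberal choice, mirrored here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionReport",
    "icc_2_1",
    "icc_filter",
    "reliability_filter",
    "redundancy_filter",
    "univariate_filter",
    "lasso_select",
    "u_statistic_ranker",
    "run_cascade",
]


@dataclass
class SelectionReport:
    stage: str
    features_in: int
    features_out: int
    selected: list
    statistics: pd.DataFrame  # per-feature statistic(s) + kept flag + reason
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.features_out > self.features_in:
            raise ValueError("selection cannot add features")


def icc_2_1(measurements: np.ndarray) -> float:
    """ICC(2,1) of an n×k table (rows = subjects, columns = raters/re-reads)."""
    x = np.asarray(measurements, float)
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ssr = k * ((row_m - grand) ** 2).sum()
    ssc = n * ((col_m - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        return 0.0
    return float((msr - mse) / denom)


def icc_filter(tables, threshold=0.8) -> SelectionReport:
    """Retain features whose across-table ICC(2,1) exceeds ``threshold``.

    ``tables`` are ≥2 FeatureTables (patients × features) from repeated
    delineations with identical index and columns.  Zero-variance features
    get ICC 0 and are dropped.
    """
    if len(tables) < 2:
        raise ValueError("need at least two measurement tables")
    t0 = tables[0]
    for t in tables[1:]:
        if not (t.columns.equals(t0.columns) and t.index.equals(t0.index)):
            raise ValueError("tables must share patients and feature columns")
    if len(t0) < 5:
        raise ValueError("ICC is unstable below 5 patients")
    stacked = np.stack([np.asarray(t, float) for t in tables], axis=2)  # n×f×k
    iccs = np.zeros(stacked.shape[1])
    for f in range(stacked.shape[1]):
        m = stacked[:, f, :]
        if np.allclose(m, m.flat[0]) or not np.all(np.isfinite(m)):
            iccs[f] = 0.0
        else:
            iccs[f] = icc_2_1(m)
    kept = iccs > threshold
    stats = pd.DataFrame({"icc": iccs, "kept": kept}, index=t0.columns)
    stats["reason"] = np.where(kept, "", "icc<=threshold")
    return SelectionReport(
        "icc", len(t0.columns), int(kept.sum()), list(t0.columns[kept]), stats,
        {"threshold": threshold},
    )


def reliability_filter(intra_tables, inter_tables, threshold=0.8) -> SelectionReport:
    """Require ICC > threshold for both intra- and inter-reader tables."""
    r_intra = icc_filter(intra_tables, threshold)
    r_inter = icc_filter(inter_tables, threshold)
    kept = r_intra.statistics["kept"] & r_inter.statistics["kept"]
    stats = pd.DataFrame(
        {
            "icc_intra": r_intra.statistics["icc"],
            "icc_inter": r_inter.statistics["icc"],
            "kept": kept,
        }
    )
    stats["reason"] = np.where(kept, "", "icc<=threshold")
    return SelectionReport(
        "reliability", len(kept), int(kept.sum()), list(stats.index[kept]), stats,
        {"threshold": threshold},
    )


def u_statistic_ranker(table: pd.DataFrame, labels) -> pd.Series:
    """Per-feature |U − n1·n2/2|: distance of the Mann-Whitney U statistic
    from its null mean, used to rank features during redundancy pruning."""
    y = np.asarray(labels).astype(bool)
    a = np.asarray(table, float)[y].T
    b = np.asarray(table, float)[~y].T
    res = mannwhitneyu(a, b, axis=1, method="asymptotic")
    null_mean = y.sum() * (~y).sum() / 2.0
    return pd.Series(np.abs(res.statistic - null_mean), index=table.columns)


def redundancy_filter(
    table: pd.DataFrame, labels, variance_floor=1e-8, rho_threshold=0.9, ranker=None
) -> SelectionReport:
    """Drop near-constant features, then greedily prune |Spearman ρ| > 0.9 pairs.

    Within a correlated pair the member with the weaker univariate ranking is
    dropped (ties and visit order resolved deterministically by feature name).
    The surviving set has all pairwise |ρ| ≤ the threshold.
    """
    variances = table.var(axis=0, ddof=1)
    stats = pd.DataFrame(index=table.columns)
    stats["variance"] = variances
    alive = variances > variance_floor
    reason = pd.Series("", index=table.columns)
    reason[~alive] = "low_variance"

    rank = (
        ranker if ranker is not None else u_statistic_ranker(table.loc[:, alive], labels)
    )
    cols = sorted(table.columns[alive])
    if len(cols) > 1:
        sub = table[cols]
        rs = spearmanr(sub.to_numpy(), axis=0).statistic
        if np.ndim(rs) == 0:  # scipy collapses the 2-column case to a scalar
            rho = np.array([[0.0, rs], [rs, 0.0]])
        else:
            rho = np.asarray(rs).copy()
            np.fill_diagonal(rho, 0.0)
        idx = {c: i for i, c in enumerate(cols)}
        # visit strongest-ranked first; keep a feature only if it is not too
        # correlated with anything already kept
        visit = sorted(cols, key=lambda f: (-rank.get(f, 0.0), f))
        kept_so_far = []
        for c in visit:
            if any(abs(rho[idx[c], idx[d]]) > rho_threshold for d in kept_so_far):
                alive[c] = False
                reason[c] = "correlated"
            else:
                kept_so_far.append(c)
    stats["max_abs_rho"] = 0.0
    stats["kept"] = alive
    stats["reason"] = reason
    selected = [c for c in table.columns if alive[c]]
    return SelectionReport(
        "redundancy", table.shape[1], len(selected), selected, stats,
        {"variance_floor": variance_floor, "rho_threshold": rho_threshold},
    )


def univariate_filter(table: pd.DataFrame, labels, alpha=0.05) -> SelectionReport:
    """Two-sided Mann-Whitney U per feature; retain p < alpha (no correction)."""
    y = np.asarray(labels).astype(bool)
    if y.sum() < 3 or (~y).sum() < 3:
        raise ValueError("each outcome class needs at least 3 patients")
    x = np.asarray(table, float)
    pvals = np.ones(x.shape[1])
    const = np.nanstd(x, axis=0) == 0
    var_cols = np.where(~const)[0]
    if var_cols.size:
        res = mannwhitneyu(
            x[np.ix_(y, var_cols)].T, x[np.ix_(~y, var_cols)].T, axis=1,
            method="asymptotic",
        )
        pvals[var_cols] = res.pvalue
    kept = pvals < alpha
    stats = pd.DataFrame({"p_value": pvals, "kept": kept}, index=table.columns)
    stats["reason"] = np.where(kept, "", np.where(const, "constant", "p>=alpha"))
    return SelectionReport(
        "univariate", table.shape[1], int(kept.sum()), list(table.columns[kept]),
        stats, {"alpha": alpha},
    )


def lasso_select(
    table: pd.DataFrame, labels, n_folds=10, seed=0, Cs=20, rule="min"
) -> SelectionReport:
    """L1-penalized logistic regression; λ by stratified k-fold CV deviance.

    Features are standardized with training statistics before fitting;
    reported coefficients are on the standardized scale.  Selected features
    are the nonzero coefficients at the chosen λ (minimum mean CV deviance).
    """
    y = np.asarray(labels).astype(int)
    x = np.asarray(table, float)
    mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    n_folds = min(n_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=max(2, n_folds), shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=Cs,
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=5000,
        refit=True,
        random_state=seed,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", FutureWarning)
        model.fit(xs, y)
    if not np.all(np.isfinite(model.coef_)):
        raise RuntimeError("LASSO path failed to converge; inspect feature scaling")
    coefs = pd.Series(model.coef_.ravel(), index=table.columns)
    kept = coefs != 0
    stats = pd.DataFrame({"coefficient": coefs, "kept": kept})
    stats["reason"] = np.where(kept, "", "shrunk_to_zero")
    return SelectionReport(
        "lasso", table.shape[1], int(kept.sum()), list(table.columns[kept]), stats,
        {"C": float(model.C_[0]), "n_folds": n_folds, "rule": rule},
    )


def run_cascade(
    table,
    labels,
    intra_tables=None,
    inter_tables=None,
    icc_threshold=0.8,
    variance_floor=1e-8,
    rho_threshold=0.9,
    alpha=0.05,
    n_folds=10,
    seed=0,
):
    """Full cascade on one feature set; returns the stage reports in order."""
    reports = []
    current = table
    if intra_tables is not None and inter_tables is not None:
        rel = reliability_filter(
            [current] + list(intra_tables), [current] + list(inter_tables), icc_threshold
        )
        reports.append(rel)
        current = current[rel.selected]
    red = redundancy_filter(current, labels, variance_floor, rho_threshold)
    reports.append(red)
    current = current[red.selected]
    uni = univariate_filter(current, labels, alpha)
    reports.append(uni)
    current = current[uni.selected]
    if current.shape[1] == 0:
        return reports, current
    las = lasso_select(current, labels, n_folds=n_folds, seed=seed)
    reports.append(las)
    return reports, current[las.selected]
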