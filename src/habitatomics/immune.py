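"""Transcriptomic / immune association stage.

Bulk expression flows: raw counts → TPM → log2(TPM+1) → (a) moderated-t
differential expression between model-score groups, (b) preranked GSEA,
(c) marker-based immune indices and their Spearman correlation with selected
radiomics features, (d) per-sample ssGSEA scoring of a B-cell gene set.
Single-cell composition flows: cell-type × patient counts → Ro/e enrichment
and rank-sum group comparisons.

The differential-expression test is a from-scratch moderated t: per-gene
two-sample statistics with an empirical-Bayes shrunken variance whose
scaled-inverse-chi-square prior (d0, s0²) is fitted by moment matching of
the per-gene sample variances against their marginal scaled-F distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "load_marker_panels",
    "tpm_normalize",
    "differential_expression",
    "gsea_preranked",
    "marker_index",
    "correlate_features_immune",
    "ssgsea_score",
    "roe",
    "compare_groups",
    "benjamini_hochberg",
]


@dataclass
class ExpressionMatrix:
    """genes × samples abundance table (counts or TPM) with group labels."""

    values: pd.DataFrame
    gene_lengths_kb: pd.Series = None
    groups: pd.Series = None
    is_tpm: bool = False

    def __post_init__(self):
        if (np.asarray(self.values) < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("gene identifiers must be unique")
        if self.is_tpm:
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1e6, atol=1e-3):
                raise ValueError("TPM columns must sum to 1e6")

    def log2p1(self) -> pd.DataFrame:
        return np.log2(self.values + 1.0)

    def to_tsv(self, path):
        self.values.to_csv(path, sep="\t")


@dataclass
class GeneSet:
    name: str
    genes: tuple

    def present_in(self, universe) -> list:
        u = set(universe)
        return [g for g in self.genes if g in u]


def load_marker_panels() -> dict:
    """Shipped marker panels (cell type → gene list)."""
    with resources.files("habitatomics.data").joinpath("marker_panels.json").open() as fh:
        raw = json.load(fh)
    return {k: list(v) for k, v in raw.items() if not k.startswith("_")}


def tpm_normalize(counts: pd.DataFrame, gene_lengths_kb: pd.Series) -> ExpressionMatrix:
    """TPM_g = 1e6 · (c_g / L_g) / Σ_j (c_j / L_j) per sample."""
    lengths = gene_lengths_kb.reindex(counts.index)
    if lengths.isna().any():
        raise KeyError("gene lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    libs = rate.sum(axis=0)
    if (libs <= 0).any():
        raise ValueError("zero library: a sample has no length-normalized counts")
    tpm = rate.div(libs, axis=1) * 1e6
    return ExpressionMatrix(tpm, gene_lengths_kb=lengths, is_tpm=True)


def benjamini_hochberg(pvals) -> np.ndarray:
    p = np.asarray(pvals, float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out


def _fit_variance_prior(s2, d):
    """Moment-match (d0, s0²) of the scaled-F marginal of sample variances."""
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    m1 = s2.mean()
    v = s2.var(ddof=1) / m1**2
    if v * d <= 2:
        return np.inf, float(m1)
    d0 = (2 * d - 4 + 4 * v * d) / (v * d - 2)
    if d0 <= 4:
        d0 = 4.01
    s0_2 = m1 * (d0 - 2) / d0
    return float(d0), float(s0_2)


def differential_expression(expr, groups=None, alpha=0.05) -> pd.DataFrame:
    """Per-gene moderated two-sample test on log2(TPM+1) values.

    Parameters
    ----------
    expr : ExpressionMatrix (TPM or counts+lengths) or DataFrame of
        log2-scale values
    groups : per-sample 0/1 labels (1 = "high" model-score group); taken from
        ``expr.groups`` when omitted

    Returns a table with log-fold-change (high − low), moderated t, raw p,
    and BH-adjusted p, sorted by p.  Genes constant across all samples get
    p = 1.
    """
    if isinstance(expr, ExpressionMatrix):
        if groups is None:
            groups = expr.groups
        x = expr.log2p1() if expr.is_tpm else np.log2(expr.values + 1.0)
    else:
        x = pd.DataFrame(expr)
    g = np.asarray(groups, int)
    hi, lo = g == 1, g == 0
    n1, n0 = int(hi.sum()), int(lo.sum())
    if min(n1, n0) < 3:
        raise ValueError("both groups need at least 3 samples")
    a = np.asarray(x, float)
    m1 = a[:, hi].mean(axis=1)
    m0 = a[:, lo].mean(axis=1)
    v1 = a[:, hi].var(axis=1, ddof=1)
    v0 = a[:, lo].var(axis=1, ddof=1)
    d = n1 + n0 - 2
    s2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / d
    d0, s0_2 = _fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.where(s2 > 0, s2, s0_2)
        df_total = d
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d + d0
    lfc = m1 - m0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df_total)
    constant = (s2 == 0) & (lfc == 0)
    p = np.where(constant, 1.0, p)
    out = pd.DataFrame(
        {
            "log2_fc": lfc,
            "t": t,
            "p_value": p,
            "p_adjusted": benjamini_hochberg(p),
            "significant": p < alpha,
        },
        index=x.index,
    )
    return out.sort_values("p_value")


# ---------------------------------------------------------------------------
# GSEA


def _enrichment_score(order_weights, in_set_mask, exponent=1.0):
    """Weighted KS running-sum ES for one ranking (signed max deviation)."""
    w = np.abs(order_weights) ** exponent
    n = w.size
    k = int(in_set_mask.sum())
    w_in = np.where(in_set_mask, w, 0.0)
    total_in = w_in.sum()
    if total_in == 0 or k == 0 or k == n:
        return 0.0
    p_hit = np.cumsum(w_in) / total_in
    p_miss = np.cumsum(~in_set_mask) / (n - k)
    run = p_hit - p_miss
    return float(run[np.argmax(np.abs(run))])


def gsea_preranked(scores: pd.Series, gene_set, n_permutations=1000, weight=1.0, seed=0):
    """Preranked GSEA of one gene set against a ranked score list.

    ES is the weighted Kolmogorov-Smirnov running-sum statistic over genes
    sorted by decreasing score; the null is gene-label permutation (random
    sets of equal size); NES = ES / mean(|ES_perm| of the same sign) and the
    p-value is the same-sign permutation tail probability.
    """
    scores = pd.Series(scores).astype(float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if scores.index.duplicated().any():
        raise ValueError("gene identifiers must be unique")
    genes = list(gene_set.genes) if isinstance(gene_set, GeneSet) else list(gene_set)
    universe = scores.index
    members = [g for g in genes if g in set(universe)]
    if len(members) < 2:
        raise ValueError("gene set intersects the universe in fewer than 2 genes")
    order = scores.sort_values(ascending=False)
    in_set = order.index.isin(members)
    es = _enrichment_score(order.to_numpy(), in_set, exponent=weight)
    rng = np.random.default_rng(seed)
    n = len(order)
    k = len(members)
    w = np.abs(order.to_numpy()) ** weight
    es_perm = np.empty(n_permutations)
    for b in range(n_permutations):
        mask = np.zeros(n, bool)
        mask[rng.choice(n, size=k, replace=False)] = True
        w_in = np.where(mask, w, 0.0)
        total = w_in.sum()
        if total == 0:
            es_perm[b] = 0.0
            continue
        run = np.cumsum(w_in) / total - np.cumsum(~mask) / (n - k)
        es_perm[b] = run[np.argmax(np.abs(run))]
    same_sign = es_perm * np.sign(es) > 0 if es != 0 else np.ones(n_permutations, bool)
    denom = np.abs(es_perm[same_sign]).mean() if same_sign.any() else np.nan
    nes = es / denom if denom and np.isfinite(denom) else 0.0
    if es == 0:
        p = 1.0
    else:
        p = (np.sum(np.abs(es_perm[same_sign]) >= abs(es)) + 1) / (same_sign.sum() + 1)
    return float(es), float(nes), float(p)


def ssgsea_score(expr, gene_set, exponent=0.25, normalize=True) -> pd.Series:
    """Per-sample single-sample GSEA score of one gene set.

    For each sample, genes are ranked by expression; the score is the sum of
    the running difference between the weighted in-set ECDF (rank weights
    ``rank**exponent``) and the unweighted out-of-set ECDF.  Scores are
    min-max normalized across the cohort by default.
    """
    x = expr.log2p1() if isinstance(expr, ExpressionMatrix) else pd.DataFrame(expr)
    genes = list(gene_set.genes) if isinstance(gene_set, GeneSet) else list(gene_set)
    members = [g for g in genes if g in set(x.index)]
    if len(members) < 2:
        raise ValueError("gene set intersects the universe in fewer than 2 genes")
    n = x.shape[0]
    in_set = x.index.isin(members)
    scores = {}
    for col in x.columns:
        vals = x[col].to_numpy()
        order = np.argsort(-vals, kind="mergesort")
        mask = in_set[order]
        ranks = np.arange(1, n + 1, dtype=float)
        w = np.where(mask, ranks[::-1] ** exponent, 0.0)  # high expression = high weight
        total_in = w.sum()
        k = mask.sum()
        p_hit = np.cumsum(w) / total_in
        p_miss = np.cumsum(~mask) / (n - k)
        scores[col] = float(np.sum(p_hit - p_miss))
    s = pd.Series(scores)
    if normalize:
        rng_ = s.max() - s.min()
        s = (s - s.min()) / rng_ if rng_ > 0 else s * 0.0
    return s


# ---------------------------------------------------------------------------
# marker indices, correlations, composition


def marker_index(expr, marker_sets=None) -> pd.DataFrame:
    """MCPcounter-style abundance index: mean log2(TPM+1) of marker genes.

    Returns cell types × samples; a cell type with no marker present in the
    universe gets an all-NaN row (flagged, not dropped).
    """
    x = expr.log2p1() if isinstance(expr, ExpressionMatrix) else pd.DataFrame(expr)
    marker_sets = marker_sets or load_marker_panels()
    rows = {}
    for ctype, genes in marker_sets.items():
        present = [g for g in genes if g in x.index]
        rows[ctype] = x.loc[present].mean(axis=0) if present else pd.Series(np.nan, index=x.columns)
    return pd.DataFrame(rows).T


def correlate_features_immune(radiomics: pd.DataFrame, indices: pd.DataFrame, log_normalize=False):
    """Pairwise Spearman ρ between immune indices and radiomics features.

    ``radiomics`` is features × patients or patients × features (auto-aligned
    on shared patient identifiers, ≥ 10 required); ``indices`` is cell types
    × patients.  Constant vectors yield NaN entries, flagged in the second
    return value.  ``log_normalize`` applies the monotone display transform
    sign(ρ)·log2(1+|ρ|).
    """
    if not set(indices.columns) & set(radiomics.columns):
        radiomics = radiomics.T  # accept patients × features
    shared = [p for p in indices.columns if p in radiomics.columns]
    if len(shared) < 10:
        raise ValueError("need at least 10 shared patients")
    rad = radiomics[shared]
    idx = indices[shared]
    rho = pd.DataFrame(index=idx.index, columns=rad.index, dtype=float)
    flags = pd.DataFrame(False, index=idx.index, columns=rad.index)
    for ct in idx.index:
        a = idx.loc[ct].to_numpy(float)
        for ft in rad.index:
            b = rad.loc[ft].to_numpy(float)
            if np.nanstd(a) == 0 or np.nanstd(b) == 0 or np.isnan(a).all():
                flags.loc[ct, ft] = True
                continue
            rho.loc[ct, ft] = stats.spearmanr(a, b).statistic
    if log_normalize:
        rho = np.sign(rho) * np.log2(1.0 + rho.abs())
    return rho, flags


def roe(counts: pd.DataFrame, groups=None) -> pd.DataFrame:
    """Ratio of observed to expected cell counts under independence.

    ``counts`` is cell types × patients (aggregated by ``groups`` into
    cell types × groups) or directly cell types × groups when ``groups`` is
    None.  Expected(c,g) = row_total·col_total/grand_total; zero margins
    yield NaN entries.
    """
    if groups is not None:
        groups = pd.Series(np.asarray(groups), index=counts.columns)
        agg = counts.T.groupby(groups).sum().T
    else:
        agg = counts.copy()
    obs = np.asarray(agg, float)
    rt = obs.sum(axis=1, keepdims=True)
    ct = obs.sum(axis=0, keepdims=True)
    grand = obs.sum()
    if grand == 0:
        raise ValueError("empty table")
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rt @ ct / grand
        out = np.where(expected > 0, obs / expected, np.nan)
    return pd.DataFrame(out, index=agg.index, columns=agg.columns)


def compare_groups(scores, groups):
    """Two-sided Wilcoxon rank-sum comparison of per-sample scores.

    Exact null distribution for ≤ 10 per group, normal approximation with
    tie correction otherwise.  Returns (p, direction) where direction is the
    sign of median(high) − median(low).
    """
    scores = np.asarray(scores, float)
    g = np.asarray(groups, int)
    hi, lo = scores[g == 1], scores[g == 0]
    if hi.size < 3 or lo.size < 3:
        raise ValueError("both groups need at least 3 samples")
    method = "exact" if max(hi.size, lo.size) <= 10 and not _has_ties(scores) else "asymptotic"
    res = stats.mannwhitneyu(hi, lo, alternative="two-sided", method=method)
    direction = float(np.sign(np.median(hi) - np.median(lo)))
    return float(res.pvalue), direction


def _has_ties(x):
    return np.unique(x).size < len(x)
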