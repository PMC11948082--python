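"""Transcriptomic stage: TPM, moderated t, GSEA/ssGSEA, indices, Ro/e."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, rankdata, spearmanr

from habitatomics.immune import (
    ExpressionMatrix,
    compare_groups,
    correlate_features_immune,
    differential_expression,
    gsea_preranked,
    load_marker_panels,
    marker_index,
    roe,
    ssgsea_score,
    tpm_normalize,
)
from habitatomics.synthetic import generate_celltype_table, generate_expression


class TestTPM:
    def test_hand_arithmetic(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series([1.0, 2.0], index=["g1", "g2"])
        em = tpm_normalize(counts, lengths)
        assert em.values.loc["g1", "s1"] == pytest.approx(2e6 / 3)
        assert em.values.loc["g2", "s1"] == pytest.approx(1e6 / 3)

    def test_symmetry(self):
        counts = pd.DataFrame(np.full((5, 3), 7.0))
        lengths = pd.Series(np.full(5, 2.0))
        em = tpm_normalize(counts, lengths)
        assert np.allclose(em.values, 1e6 / 5)

    def test_zero_length_rejected(self):
        counts = pd.DataFrame({"s": [1, 1]}, index=["a", "b"])
        with pytest.raises(ValueError):
            tpm_normalize(counts, pd.Series([1.0, 0.0], index=["a", "b"]))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_columns_sum_to_million(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(rng.integers(1, 1000, size=(20, 4)).astype(float))
        lengths = pd.Series(rng.uniform(0.2, 10, 20))
        em = tpm_normalize(counts, lengths)
        assert np.allclose(em.values.sum(axis=0), 1e6, atol=1e-3)


class TestDifferentialExpression:
    def test_null_p_values_uniform(self):
        em = generate_expression(n_genes=5000, n_samples=40, shift=0.0, seed=9)
        tpm = tpm_normalize(em.values, em.gene_lengths_kb)
        tpm.groups = em.groups
        table = differential_expression(tpm, em.groups)
        ks = kstest(table["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_markers_rank_high(self):
        markers = [f"G{i:05d}" for i in range(0, 500, 20)]
        em = generate_expression(
            n_genes=3000, n_samples=40, marker_sets={"B": markers}, shift=1.0, seed=4
        )
        tpm = tpm_normalize(em.values, em.gene_lengths_kb)
        table = differential_expression(tpm, em.groups)
        ranks = pd.Series(np.arange(len(table)), index=table.index)[markers]
        assert ranks.median() < 0.05 * len(table)
        assert (table.loc[markers, "log2_fc"] > 0).mean() > 0.9

    def test_constant_gene_p_one(self):
        x = pd.DataFrame(
            np.vstack([np.ones(12), np.random.default_rng(0).normal(size=12)]),
            index=["flat", "noisy"],
        )
        table = differential_expression(x, np.repeat([0, 1], 6))
        assert table.loc["flat", "p_value"] == 1.0

    def test_group_size_precondition(self):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 6)))
        with pytest.raises(ValueError):
            differential_expression(x, [0, 0, 1, 1, 1, 1])


class TestGSEA:
    def _scores(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        s = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        return s.sort_values(ascending=False)

    def test_top_k_set_es_near_one(self):
        scores = self._scores()
        top = list(scores.index[:20])
        es, nes, p = gsea_preranked(scores, top, n_permutations=200, seed=1)
        assert es >= 0.95
        assert p < 0.02

    def test_reversed_ranking_negates_es(self):
        scores = self._scores(seed=2)
        genes = list(scores.index[::50])
        es_fwd, *_ = gsea_preranked(scores, genes, n_permutations=50, seed=0)
        es_rev, *_ = gsea_preranked(-scores, genes, n_permutations=50, seed=0)
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)

    def test_small_intersection_rejected(self):
        scores = self._scores()
        with pytest.raises(ValueError):
            gsea_preranked(scores, ["absent1", "absent2"], n_permutations=10)

    def test_random_set_not_significant_on_average(self):
        scores = self._scores(seed=3)
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(20):
            genes = list(rng.choice(scores.index, 25, replace=False))
            *_, p = gsea_preranked(scores, genes, n_permutations=99, seed=5)
            ps.append(p)
        assert np.mean(ps) > 0.3


class TestMarkerIndex:
    def test_equal_expression_identity(self):
        panels = {"B": ["CD19", "MS4A1"]}
        x = pd.DataFrame(
            np.full((2, 4), 3.0), index=["CD19", "MS4A1"],
            columns=list("abcd"),
        )
        idx = marker_index(x, panels)
        assert np.allclose(idx.loc["B"], 3.0)

    def test_missing_panel_flagged_nan(self):
        x = pd.DataFrame(np.ones((2, 3)), index=["g1", "g2"])
        idx = marker_index(x, {"B": ["CD19"]})
        assert idx.loc["B"].isna().all()

    def test_planted_shift_detected(self):
        panels = load_marker_panels()
        genes = [f"G{i:05d}" for i in range(1990)] + [
            "CD19", "CD79A", "MS4A1", "IGHM", "IGHG1", "IGHG2",
        ]
        em = generate_expression(n_genes=1996, n_samples=60, shift=2.0, seed=6)
        em.values.index = genes
        em.gene_lengths_kb.index = genes
        # shift the B markers manually in the high group
        hi = (em.groups == 1).values
        em.values.loc[panels["B"], em.values.columns[hi]] *= 4.0
        tpm = tpm_normalize(em.values, em.gene_lengths_kb)
        idx = marker_index(tpm)
        p, direction = compare_groups(idx.loc["B"], em.groups.to_numpy())
        assert p < 0.05 and direction > 0


class TestCorrelation:
    def test_monotone_transform_rho_one(self):
        idx = pd.DataFrame(
            [np.linspace(1, 2, 12)], index=["B"], columns=[f"p{i}" for i in range(12)]
        )
        rad = pd.DataFrame(
            [np.exp(np.linspace(1, 2, 12))], index=["feat"],
            columns=[f"p{i}" for i in range(12)],
        )
        rho, flags = correlate_features_immune(rad, idx)
        assert rho.loc["B", "feat"] == pytest.approx(1.0)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        rad = pd.DataFrame(
            rng.normal(size=(4, 30)), index=[f"f{i}" for i in range(4)],
            columns=[f"p{i}" for i in range(30)],
        )
        idx = pd.DataFrame(
            rng.normal(size=(2, 30)), index=["B", "T"], columns=rad.columns
        )
        rho, _ = correlate_features_immune(rad, idx)
        for ct in idx.index:
            for ft in rad.index:
                oracle = np.corrcoef(
                    rankdata(idx.loc[ct]), rankdata(rad.loc[ft])
                )[0, 1]
                assert abs(rho.loc[ct, ft] - oracle) < 1e-12

    def test_constant_vector_flagged(self):
        rad = pd.DataFrame(
            [np.ones(12)], index=["flat"], columns=[f"p{i}" for i in range(12)]
        )
        idx = pd.DataFrame(
            [np.arange(12.0)], index=["B"], columns=rad.columns
        )
        rho, flags = correlate_features_immune(rad, idx)
        assert flags.loc["B", "flat"]
        assert np.isnan(rho.loc["B", "flat"])

    def test_minimum_shared_patients(self):
        rad = pd.DataFrame([np.arange(5.0)], index=["f"], columns=list("abcde"))
        idx = pd.DataFrame([np.arange(5.0)], index=["B"], columns=list("abcde"))
        with pytest.raises(ValueError):
            correlate_features_immune(rad, idx)


class TestSsGSEA:
    def test_top_ranked_sample_maximal(self):
        genes = [f"g{i}" for i in range(100)]
        x = pd.DataFrame(
            np.random.default_rng(0).uniform(1, 2, size=(100, 5)),
            index=genes, columns=list("abcde"),
        )
        members = genes[:10]
        x.loc[members, "c"] = 50.0  # set genes dominate sample c
        scores = ssgsea_score(x, members)
        assert scores.idxmax() == "c"
        assert scores.max() == 1.0  # min-max normalized

    def test_identical_samples_identical_scores(self):
        x = pd.DataFrame(
            np.tile(np.random.default_rng(1).uniform(1, 5, 50)[:, None], (1, 3)),
            index=[f"g{i}" for i in range(50)], columns=list("xyz"),
        )
        scores = ssgsea_score(x, [f"g{i}" for i in range(5)], normalize=False)
        assert scores.nunique() == 1

    def test_planted_shift_raises_scores(self):
        markers = [f"G{i:05d}" for i in range(30)]
        em = generate_expression(
            n_genes=2000, n_samples=60, marker_sets={"B": markers}, shift=2.0, seed=8
        )
        tpm = tpm_normalize(em.values, em.gene_lengths_kb)
        scores = ssgsea_score(tpm, markers)
        p, direction = compare_groups(scores, em.groups.to_numpy())
        assert p < 0.01 and direction > 0


class TestRoe:
    def test_hand_arithmetic_2x2(self):
        t = pd.DataFrame([[30, 10], [10, 30]], index=["B", "T"], columns=["hi", "lo"])
        r = roe(t)
        assert r.loc["B", "hi"] == pytest.approx(1.5)
        assert r.loc["B", "lo"] == pytest.approx(0.5)
        assert r.loc["T", "hi"] == pytest.approx(0.5)

    def test_independent_composition_all_ones(self):
        t = pd.DataFrame([[20, 40], [10, 20], [5, 10]], columns=["a", "b"])
        assert np.allclose(roe(t), 1.0)

    def test_margin_conservation(self):
        counts, groups = generate_celltype_table(n_patients=20, seed=3)
        r = roe(counts, groups)
        agg = counts.T.groupby(groups.to_numpy()).sum().T
        weights = agg.sum(axis=0) / agg.sum().sum()
        weighted = (r * weights).sum(axis=1)
        assert np.allclose(weighted, 1.0)


class TestCompareGroups:
    def test_exact_toy_p(self):
        p, direction = compare_groups([4, 5, 6, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert p == pytest.approx(0.1)
        assert direction > 0

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        g = rng.integers(0, 2, 30)
        while g.min() == g.max():
            g = rng.integers(0, 2, 30)
        p1, d1 = compare_groups(s, g)
        p2, d2 = compare_groups(s, 1 - g)
        assert p1 == pytest.approx(p2)
        assert d1 == -d2 or (d1 == 0 and d2 == 0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], [1, 1, 1])
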