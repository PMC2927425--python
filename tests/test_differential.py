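"""Differential statistics against hand computations and oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dietmap import differential as dd
from dietmap.simulate import SimulationConfig, generate_expression
from dietmap.study import ExpressionStudy

import oracles


# -- quantile normalization ---------------------------------------------------

class TestQuantileNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = dd.quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)

    def test_two_column_hand_example(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = dd.quantile_normalize(m)
        expected = [2.5, 3.5, 4.5]
        assert list(out["a"]) == expected
        assert list(out["b"]) == expected

    def test_matches_sorting_oracle_on_random_tie_free_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = pd.DataFrame(rng.normal(size=(15, 4)))
            out = dd.quantile_normalize(m)
            exp = oracles.quantile_normalize_small([list(m[c]) for c in m])
            assert np.allclose(out.to_numpy(), np.array(exp).T)

    def test_ties_stay_tied(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
        out = dd.quantile_normalize(m)
        assert out["a"][0] == out["a"][1]

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(50, 6)))
        once = dd.quantile_normalize(m)
        twice = dd.quantile_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


# -- SVD ----------------------------------------------------------------------

class TestSvd:
    def test_rank_one_matrix_has_one_singular_value(self, tiny_study):
        u = np.arange(1, 5, dtype=float)[:, None]
        v = np.arange(1, 13, dtype=float)[None, :]
        expr = pd.DataFrame(u @ v, index=tiny_study.expression.index,
                            columns=tiny_study.expression.columns)
        svd = dd.svd_overview(tiny_study.with_expression(expr))
        assert svd.singular_values[0] > 0
        assert (svd.singular_values[1:] < 1e-10 * svd.singular_values[0]).all()

    def test_variance_fractions_sum_to_one(self, default_study):
        study, _ = default_study
        svd = dd.svd_overview(study)
        assert abs(svd.variance_fraction.sum() - 1.0) < 1e-9

    def test_constant_matrix_degenerates_quietly(self, tiny_study):
        expr = tiny_study.expression * 0 + 5.0
        svd = dd.svd_overview(tiny_study.with_expression(expr))
        assert np.allclose(svd.singular_values, 0.0)

    def test_component_one_separates_tissues(self, default_study):
        study, _ = default_study
        svd = dd.svd_overview(study)
        pc1 = svd.sample_loadings["PC1"]
        ranges = sorted((pc1[study.samples["tissue"] == t].min(),
                         pc1[study.samples["tissue"] == t].max())
                        for t in study.tissues)
        for (lo1, hi1), (lo2, hi2) in zip(ranges, ranges[1:]):
            assert hi1 < lo2


# -- t-tests ------------------------------------------------------------------

class TestPerTissueTtest:
    def test_symmetric_equal_groups_give_t0_p1(self):
        rows, vals = [], []
        for t in ["liver"]:
            for g in ["beef", "herring"]:
                for r in range(1, 4):
                    rows.append((f"{t}_{g}_r{r}", t, g, r))
                    vals.append([1.0, 2.0, 3.0][r - 1])
        meta = pd.DataFrame(rows, columns=["sample_id", "tissue", "group", "replicate"]
                            ).set_index("sample_id")
        expr = pd.DataFrame([vals], index=pd.Index(["g1"], name="gene_id"),
                            columns=meta.index)
        tab = dd.per_tissue_ttest(ExpressionStudy(expr, meta), "liver")
        assert tab.loc["g1", "t_stat"] == 0.0
        assert tab.loc["g1", "p_value"] == 1.0

    def test_matches_textbook_formula_and_scipy(self):
        x1, x2 = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t_o, p_o = oracles.student_t_3v3(x1, x2)
        rows = [(f"liver_beef_r{r}", "liver", "beef", r) for r in (1, 2, 3)]
        rows += [(f"liver_herring_r{r}", "liver", "herring", r) for r in (1, 2, 3)]
        meta = pd.DataFrame(rows, columns=["sample_id", "tissue", "group", "replicate"]
                            ).set_index("sample_id")
        expr = pd.DataFrame([x1 + x2], index=pd.Index(["g1"], name="gene_id"),
                            columns=meta.index)
        tab = dd.per_tissue_ttest(ExpressionStudy(expr, meta), "liver")
        assert tab.loc["g1", "t_stat"] == pytest.approx(t_o, abs=1e-12)
        assert tab.loc["g1", "p_value"] == pytest.approx(p_o, abs=1e-12)
        sp = stats.ttest_ind(x2, x1)
        assert tab.loc["g1", "t_stat"] == pytest.approx(sp.statistic, abs=1e-12)
        assert tab.loc["g1", "log2fc"] == pytest.approx(3.0)

    def test_null_type_one_error_near_nominal(self):
        study, _ = generate_expression(SimulationConfig(diet_effect_size=0.0, seed=13))
        tab = dd.per_tissue_ttest(study, "muscle")
        frac = float((tab["p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_zero_variance_gene_with_different_means_is_clamped(self):
        rows = [(f"liver_beef_r{r}", "liver", "beef", r) for r in (1, 2, 3)]
        rows += [(f"liver_herring_r{r}", "liver", "herring", r) for r in (1, 2, 3)]
        meta = pd.DataFrame(rows, columns=["sample_id", "tissue", "group", "replicate"]
                            ).set_index("sample_id")
        expr = pd.DataFrame([[1.0] * 3 + [2.0] * 3, [1.0] * 6],
                            index=pd.Index(["g1", "g2"], name="gene_id"),
                            columns=meta.index)
        tab = dd.per_tissue_ttest(ExpressionStudy(expr, meta), "liver")
        assert tab.loc["g1", "p_value"] == dd.P_EPS
        assert tab.loc["g2", "p_value"] == 1.0


# -- ANOVA --------------------------------------------------------------------

class TestTwoWayAnova:
    @staticmethod
    def _study_from_cells(y: np.ndarray) -> ExpressionStudy:
        a, b, n = y.shape[1:]
        tissues = [f"t{i}" for i in range(a)]
        groups = ["beef", "herring"][:b]
        rows, cols = [], []
        for i, t in enumerate(tissues):
            for j, g in enumerate(groups):
                for r in range(n):
                    rows.append((f"{t}_{g}_r{r}", t, g, r))
        meta = pd.DataFrame(rows, columns=["sample_id", "tissue", "group", "replicate"]
                            ).set_index("sample_id")
        expr = pd.DataFrame(y.reshape(y.shape[0], -1),
                            index=pd.Index([f"g{i}" for i in range(y.shape[0])],
                                           name="gene_id"),
                            columns=meta.index)
        return ExpressionStudy(expr, meta)

    def test_pure_tissue_effect(self):
        y = np.zeros((1, 3, 2, 3))
        for i in range(3):
            y[0, i] = i * 10.0
        y += np.random.default_rng(0).normal(0, 1e-3, size=y.shape)
        tab = dd.two_way_anova(self._study_from_cells(y))
        assert tab["p_tissue"].iloc[0] < 1e-6
        assert tab["F_diet"].iloc[0] < 1.0

    def test_matches_sums_of_squares_oracle_on_random_designs(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(30, 3, 2, 3))
        tab = dd.two_way_anova(self._study_from_cells(y))
        for g in range(30):
            orc = oracles.two_way_anova_cellmeans(y[g])
            assert tab["F_tissue"].iloc[g] == pytest.approx(orc["A"][0], abs=1e-10)
            assert tab["p_tissue"].iloc[g] == pytest.approx(orc["A"][1], abs=1e-10)
            assert tab["F_diet"].iloc[g] == pytest.approx(orc["B"][0], abs=1e-10)
            assert tab["p_diet"].iloc[g] == pytest.approx(orc["B"][1], abs=1e-10)
            assert tab["F_interaction"].iloc[g] == pytest.approx(orc["AB"][0], abs=1e-10)
            assert tab["p_interaction"].iloc[g] == pytest.approx(orc["AB"][1], abs=1e-10)

    def test_group_relabeling_leaves_tissue_p_unchanged(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(5, 3, 2, 3))
        t1 = dd.two_way_anova(self._study_from_cells(y))
        t2 = dd.two_way_anova(self._study_from_cells(y[:, :, ::-1, :]))
        assert np.allclose(t1["p_tissue"], t2["p_tissue"], atol=1e-12)

    def test_unbalanced_design_is_rejected(self, default_study):
        study, _ = default_study
        broken = study.expression.drop(columns=[study.expression.columns[0]])
        meta = study.samples.drop(index=[study.expression.columns[0]])
        with pytest.raises(ValueError, match="unbalanced"):
            dd.two_way_anova(ExpressionStudy(broken, meta))


# -- BH -----------------------------------------------------------------------

class TestAdjustQ:
    def test_hand_example(self):
        q = dd.adjust_q([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate_inputs(self):
        assert dd.adjust_q([0.2]) == pytest.approx([0.2])
        assert np.allclose(dd.adjust_q([1.0, 1.0, 1.0]), 1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_matches_exhaustive_stepup_oracle(self, p):
        assert np.allclose(dd.adjust_q(p), oracles.bh_stepup(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        q = dd.adjust_q(p)
        _, q_sm, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            dd.adjust_q([0.1, float("nan")])


def test_significant_genes_strict_inequality():
    tab = pd.DataFrame({"q_value": [0.04, 0.05, 0.06]}, index=["a", "b", "c"])
    assert dd.significant_genes(tab, 0.05) == {"a"}
    assert dd.significant_genes(tab, 0.0) == set()


# -- circular map -------------------------------------------------------------

class TestCircularMap:
    def test_sorted_by_chromosome_then_position(self, tiny_study):
        tab = dd.per_tissue_ttest(tiny_study, "liver")
        out = dd.circular_map_export({"liver": tab}, tiny_study.genes)
        assert list(out["gene_id"]) == ["G1", "G0", "G2", "G3"]
        assert list(out["end"] - out["start"]) == [1, 1, 1, 1]

    def test_neglog10_of_q(self, tiny_study):
        tab = dd.per_tissue_ttest(tiny_study, "liver")
        tab["q_value"] = 0.05
        out = dd.circular_map_export({"liver": tab}, tiny_study.genes)
        assert np.allclose(out["neglog10q_liver"], 1.3010, atol=1e-4)

    def test_unannotated_genes_dropped(self, tiny_study, caplog):
        tab = dd.per_tissue_ttest(tiny_study, "liver")
        annotation = tiny_study.genes.drop(index=["G2"])
        out = dd.circular_map_export({"liver": tab}, annotation)
        assert len(out) == 3 and "G2" not in set(out["gene_id"])


class TestStoreyQ:
    def test_complete_null_reduces_to_bh(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=4000)
        q_bh = dd.adjust_q(p, "bh")
        q_st = dd.adjust_q(p, "storey")
        assert dd.estimate_pi0(p) > 0.9
        assert np.allclose(q_st, np.minimum(dd.estimate_pi0(p) * q_bh, 1.0))

    def test_signal_lowers_pi0_and_q(self):
        rng = np.random.default_rng(7)
        p = np.r_[rng.uniform(size=500) * 1e-4, rng.uniform(size=500)]
        pi0 = dd.estimate_pi0(p)
        assert pi0 < 0.7
        assert (dd.adjust_q(p, "storey") <= dd.adjust_q(p, "bh") + 1e-12).all()


class TestSampleDistances:
    def test_euclidean_matches_direct_computation(self, tiny_study):
        d = dd.sample_distances(tiny_study)
        x = tiny_study.expression.to_numpy().T
        i, j = 0, 5
        direct = np.sqrt(((x[i] - x[j]) ** 2).sum())
        assert d.iloc[i, j] == pytest.approx(direct, abs=1e-9)
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.allclose(np.diag(d.to_numpy()), 0.0)

    def test_replicates_cluster_by_tissue(self, default_study):
        study, _ = default_study
        d = dd.sample_distances(study, metric="correlation")
        same, other = [], []
        for s1 in study.sample_ids:
            for s2 in study.sample_ids:
                if s1 >= s2:
                    continue
                t1 = study.samples.loc[s1, "tissue"]
                (same if t1 == study.samples.loc[s2, "tissue"] else other).append(d.loc[s1, s2])
        assert max(same) < min(other)
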