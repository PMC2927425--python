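"""Adjacency, TOM, module detection and module enrichment."""

import numpy as np
import pandas as pd
import pytest

from dietmap import coexpression as cx
from dietmap.networks import FeatureNetwork
from dietmap.simulate import SimulationConfig, generate_expression

import oracles


def _random_adjacency(n, rng):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    genes = [f"g{i:02d}" for i in range(n)]
    return pd.DataFrame(a, index=genes, columns=genes)


class TestAdjacency:
    @staticmethod
    def _expr(x):
        return pd.DataFrame(x, index=[f"g{i}" for i in range(x.shape[0])])

    def test_perfect_correlation_is_one_for_any_beta(self):
        base = np.arange(8.0)
        x = np.vstack([base, 2 * base + 3])
        for beta in (1.0, 6.0, 12.0):
            a = cx.adjacency(self._expr(x), beta=beta)
            assert a.loc["g0", "g1"] == pytest.approx(1.0)

    def test_half_correlation_to_the_sixth(self):
        # construct a pair with exact Pearson correlation 0.5
        x1 = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        x2 = np.array([1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0, 1.0])
        y = x1 * np.sqrt(0.5) ** 0 * 0.5 + x2 * (np.sqrt(3) / 2)
        a = cx.adjacency(self._expr(np.vstack([x1, y])), beta=6.0)
        assert a.loc["g0", "g1"] == pytest.approx(0.5**6, abs=1e-12)
        assert a.loc["g0", "g1"] == pytest.approx(0.015625, abs=1e-12)

    def test_beta_one_equals_absolute_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 10))
        a = cx.adjacency(self._expr(x), beta=1.0)
        assert np.allclose(a.to_numpy(), np.abs(np.corrcoef(x)) - np.eye(5) * np.abs(np.corrcoef(x)).diagonal())

    def test_zero_variance_gene_dropped(self):
        x = np.vstack([np.ones(8), np.arange(8.0), np.arange(8.0)[::-1]])
        a = cx.adjacency(self._expr(x), beta=2.0)
        assert "g0" not in a.index and len(a) == 2

    def test_diagonal_zero(self):
        rng = np.random.default_rng(1)
        a = cx.adjacency(self._expr(rng.normal(size=(6, 9))), beta=6.0)
        assert np.allclose(np.diag(a.to_numpy()), 0.0)


class TestTom:
    def test_two_nodes_fully_connected(self):
        a = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        t = cx.tom(a)
        assert t.loc["a", "b"] == pytest.approx(1.0)

    def test_empty_adjacency_gives_zero_offdiagonal(self):
        a = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        t = cx.tom(a)
        off = t.to_numpy()[~np.eye(4, dtype=bool)]
        assert (off == 0.0).all()
        assert (np.diag(t.to_numpy()) == 1.0).all()

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = _random_adjacency(20, rng)
            t = cx.tom(a)
            assert np.allclose(t.to_numpy(), oracles.tom_triple_loop(a.to_numpy()),
                               atol=1e-12)

    def test_bounds_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            t = cx.tom(_random_adjacency(15, rng)).to_numpy()
            assert (t >= 0.0).all() and (t <= 1.0).all()

    def test_asymmetric_input_rejected(self):
        a = _random_adjacency(5, np.random.default_rng(4))
        a.iloc[0, 1] += 0.1
        with pytest.raises(ValueError, match="symmetric"):
            cx.tom(a)


class TestDetectModules:
    def test_single_correlated_block_is_one_module(self):
        cfg = SimulationConfig(n_genes=40, n_coexpr_blocks=1, block_size=20,
                               tissue_effect_sd=0.0, diet_effect_size=0.0,
                               n_gene_sets=3, n_planted_sets_per_tissue=0,
                               set_size_range=(3, 5), block_correlation=0.9, seed=0)
        study, truth = generate_expression(cfg)
        t = cx.tom(cx.adjacency(study.expression, beta=6.0))
        mods = cx.detect_modules(t, min_module_size=10, cut_height=0.85)
        block = set(truth.coexpr_blocks["B1"])
        labels = set(mods.loc[sorted(block), "module"])
        assert len(labels) == 1 and labels != {cx.UNASSIGNED}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        a = _random_adjacency(30, rng)
        t = cx.tom(a)
        perm = rng.permutation(30)
        t_perm = t.iloc[perm, perm]
        m1 = cx.detect_modules(t, min_module_size=3, cut_height=0.9)
        m2 = cx.detect_modules(t_perm, min_module_size=3, cut_height=0.9)
        assert m1.loc[m2.index, "module"].equals(m2["module"])

    def test_all_unassigned_is_legal(self, caplog):
        genes = [f"g{i}" for i in range(12)]
        t = pd.DataFrame(np.eye(12), index=genes, columns=genes)
        mods = cx.detect_modules(t, min_module_size=10, cut_height=0.5)
        assert (mods["module"] == cx.UNASSIGNED).all()

    def test_module_labels_ordered_by_size(self):
        cfg = SimulationConfig(n_genes=110, n_coexpr_blocks=2, block_size=40,
                               tissue_effect_sd=0.0, diet_effect_size=0.0,
                               n_gene_sets=3, n_planted_sets_per_tissue=0,
                               set_size_range=(3, 5), block_correlation=0.9, seed=1)
        study, truth = generate_expression(cfg)
        # shrink block 2 by replacing 15 of its genes with pure noise
        expr = study.expression.copy()
        drop = list(truth.coexpr_blocks["B2"])[:15]
        rng = np.random.default_rng(0)
        expr.loc[drop] = rng.normal(7, 0.3, size=(15, expr.shape[1]))
        t = cx.tom(cx.adjacency(expr, beta=6.0))
        mods = cx.detect_modules(t, min_module_size=10, cut_height=0.85)
        sizes = mods[mods["module"] != cx.UNASSIGNED]["module"].value_counts()
        labels = list(sizes.sort_values(ascending=False).index)
        assert labels[0] == "M1" and sizes["M1"] >= sizes["M2"]


class TestSelectDietGenes:
    def test_strict_cut_and_ordering(self):
        tab = pd.DataFrame({"q_diet": [0.04, 0.05, 0.01]}, index=["c", "a", "b"])
        assert cx.select_diet_genes(tab, 0.05) == ["b", "c"]
        assert cx.select_diet_genes(tab, 0.0) == []


class TestModuleEnrichment:
    def test_module_equal_to_set_hits_minimal_p(self):
        genes = [f"g{i}" for i in range(30)]
        assignment = pd.DataFrame(
            {"module": ["M1"] * 10 + [cx.UNASSIGNED] * 20},
            index=pd.Index(genes, name="gene_id"))
        sets = FeatureNetwork({"s": frozenset(genes[:10])})
        res = cx.module_enrichment(assignment, sets)
        expected = oracles.hypergeom_tail(10, 30, 10, 10)
        assert res.loc[0, "p"] == pytest.approx(expected, abs=1e-15)

    def test_disjoint_set_gives_p_one(self):
        genes = [f"g{i}" for i in range(20)]
        assignment = pd.DataFrame({"module": ["M1"] * 10 + ["M2"] * 10},
                                  index=pd.Index(genes, name="gene_id"))
        sets = FeatureNetwork({"s": frozenset(["zzz"])})
        res = cx.module_enrichment(assignment, sets)
        assert res.empty  # unresolvable set dropped entirely

    def test_planted_block_set_recovered(self):
        cfg = SimulationConfig(n_genes=120, n_coexpr_blocks=2, block_size=30,
                               tissue_effect_sd=0.0, diet_effect_size=0.0,
                               n_gene_sets=5, n_planted_sets_per_tissue=0,
                               set_size_range=(5, 20), block_correlation=0.8, seed=2)
        study, truth = generate_expression(cfg)
        t = cx.tom(cx.adjacency(study.expression, beta=6.0))
        mods = cx.detect_modules(t, min_module_size=10, cut_height=0.85)
        sets = FeatureNetwork({f"SET_BLOCK_{b}": frozenset(g)
                               for b, g in truth.coexpr_blocks.items()})
        res = cx.module_enrichment(mods, sets)
        best = res.groupby("set_id")["q"].min()
        assert (best < 0.05).all()


def test_scale_free_beta_returns_candidate():
    cfg = SimulationConfig(n_genes=100, tissue_effect_sd=0.0, diet_effect_size=0.0,
                           n_gene_sets=3, n_planted_sets_per_tissue=0,
                           set_size_range=(3, 5), seed=4)
    study, _ = generate_expression(cfg)
    beta = cx.scale_free_beta(study.expression)
    assert beta in range(1, 11)
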