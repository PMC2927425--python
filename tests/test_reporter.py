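"""Reporter scoring: transform, backgrounds, X-scores, baseline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietmap import reporter as rp
from dietmap.networks import FeatureNetwork
from dietmap.simulate import SimulationConfig, generate_expression, generate_metabolic_model

import oracles


class TestPToZ:
    def test_median_p_maps_to_zero(self):
        assert rp.p_to_z([0.5])[0] == pytest.approx(0.0, abs=1e-12)

    def test_five_percent_tail(self):
        assert rp.p_to_z([0.05])[0] == pytest.approx(1.6449, abs=1e-4)

    def test_extreme_p_clamped_finite(self):
        z = rp.p_to_z([0.0, 1.0])
        assert np.isfinite(z).all()
        assert z[0] > 8 and z[1] < -8

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rp.p_to_z([-0.1])

    def test_monotone_decreasing(self):
        p = np.linspace(0.01, 0.99, 50)
        z = rp.p_to_z(p)
        assert (np.diff(z) < 0).all()


class TestMetaboliteNeighbors:
    def test_union_semantics_toy(self):
        triples = pd.DataFrame(
            [("R1", "g1", ""), ("R1", "g2", ""), ("R2", "g2", ""), ("R2", "g3", ""),
             ("R1", "", "m"), ("R2", "", "m")],
            columns=["reaction_id", "gene_id", "metabolite_id"])
        net = rp.metabolite_neighbors(triples, min_set_size=1)
        assert net["m"] == {"g1", "g2", "g3"}

    def test_currency_fixture_excluded_at_default_cut(self):
        net, triples = generate_metabolic_model(SimulationConfig(seed=3))
        filtered = rp.metabolite_neighbors(triples)
        assert not any(m.startswith("CUR") for m in filtered.features)
        assert any(m.startswith("CUR") for m in net.features)

    def test_empty_model_warns_and_returns_empty(self, caplog):
        triples = pd.DataFrame(columns=["reaction_id", "gene_id", "metabolite_id"])
        net = rp.metabolite_neighbors(triples)
        assert len(net) == 0


class TestReporterScores:
    @staticmethod
    def _normal_universe(n=2000, seed=0):
        rng = np.random.default_rng(seed)
        # exact standard-normal sample via quantiles avoids sampling drift
        z = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        rng.shuffle(z)
        return pd.Series(z, index=[f"G{i:05d}" for i in range(n)])

    def test_known_member_z_gives_known_raw_score(self):
        z = self._normal_universe()
        members = list(z.index[:4])
        z.loc[members] = 2.0
        net = FeatureNetwork({"f": frozenset(members)})
        res = rp.reporter_scores(z, net, n_bg=10_000, min_set_size=1, seed=1)
        assert res.loc["f", "z_raw"] == pytest.approx(4.0, abs=1e-12)
        assert abs(res.loc["f", "z_corrected"] - 4.0) < 0.2

    def test_singleton_feature_identity(self):
        z = self._normal_universe(500)
        g = z.index[7]
        net = FeatureNetwork({"f": frozenset([g])})
        res = rp.reporter_scores(z, net, n_bg=100_000, min_set_size=1, seed=2)
        assert res.loc["f", "z_raw"] == pytest.approx(float(z[g]), abs=1e-12)

    def test_background_moments_standard_normal_universe(self):
        z = self._normal_universe(2000, seed=3).to_numpy()
        rng = np.random.default_rng(0)
        moments = rp._background_moments(z, np.array([1]), 100_000, rng)
        mu, sigma = moments[1]
        assert abs(mu) < 0.05
        assert abs(sigma - 1.0) < 0.05

    def test_seed_determinism_and_metadata(self):
        z = self._normal_universe(300)
        net = FeatureNetwork({"f": frozenset(z.index[:10]), "g": frozenset(z.index[5:25])})
        r1 = rp.reporter_scores(z, net, n_bg=2000, min_set_size=1, seed=9)
        r2 = rp.reporter_scores(z, net, n_bg=2000, min_set_size=1, seed=9)
        pd.testing.assert_frame_equal(r1, r2)
        assert r1.attrs["seed"] == 9 and r1.attrs["n_bg"] == 2000

    def test_adding_positive_z_gene_never_decreases_sum(self):
        z = self._normal_universe(200, seed=5)
        members = list(z.index[:8])
        extra = z.index[z.to_numpy() > 0][-1]
        n1 = FeatureNetwork({"f": frozenset(members)})
        n2 = FeatureNetwork({"f": frozenset(members + [extra])})
        r1 = rp.reporter_scores(z, n1, n_bg=1000, min_set_size=1, seed=0)
        r2 = rp.reporter_scores(z, n2, n_bg=1000, min_set_size=1, seed=0)
        s1 = r1.loc["f", "z_raw"] * np.sqrt(r1.loc["f", "k"])
        s2 = r2.loc["f", "z_raw"] * np.sqrt(r2.loc["f", "k"])
        assert s2 >= s1

    def test_degenerate_universe_raises(self):
        z = pd.Series(1.0, index=[f"G{i}" for i in range(50)])
        net = FeatureNetwork({"f": frozenset(z.index[:5])})
        with pytest.raises(ValueError, match="degenerate"):
            rp.reporter_scores(z, net, n_bg=1000, min_set_size=1, seed=0)

    def test_small_features_skipped_by_min_set_size(self):
        z = self._normal_universe(100)
        net = FeatureNetwork({"small": frozenset(z.index[:2]),
                              "ok": frozenset(z.index[:5])})
        res = rp.reporter_scores(z, net, n_bg=1000, min_set_size=3, seed=0)
        assert list(res.index) == ["ok"]


class TestSelectReporters:
    def test_zero_cut_selects_nothing(self):
        res = pd.DataFrame({"p_reporter": [0.0001, 0.5]}, index=["a", "b"])
        assert len(rp.select_reporters(res, 0.0)) == 0

    def test_strict_cut_and_tie_break_by_id(self):
        res = pd.DataFrame({"p_reporter": [0.0005, 0.0005, 0.001, 0.0001]},
                           index=["b", "a", "c", "d"])
        sel = rp.select_reporters(res, 0.001)
        assert list(sel.index) == ["d", "a", "b"]


class TestXScores:
    def test_grand_mean_is_zero_for_any_feature(self, default_study):
        study, truth = default_study
        net = FeatureNetwork({"f": truth.planted_sets["liver"][0].members})
        xs = rp.x_scores(study, net)
        # equal group sizes -> plain mean over the 6 tissue x diet cells
        assert xs.loc["f"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_planted_up_set_scores_higher_in_herring(self, default_study):
        study, truth = default_study
        up = next(ps for ps in truth.planted_sets["liver"] if ps.direction == "up")
        xs = rp.x_scores(study, FeatureNetwork({"f": up.members}))
        assert xs.loc["f", "liver|herring"] > xs.loc["f", "liver|beef"]

    def test_tissue_grouping_yields_three_columns(self, default_study):
        study, truth = default_study
        net = FeatureNetwork({"f": truth.planted_sets["liver"][0].members})
        xs = rp.x_scores(study, net, grouping="tissue")
        assert list(xs.columns) == ["liver", "muscle", "wat"]

    def test_constant_gene_rows_are_excluded(self, tiny_study, caplog):
        expr = tiny_study.expression.copy()
        expr.loc["G0"] = 3.0
        study = tiny_study.with_expression(expr)
        xs = rp.x_scores(study, FeatureNetwork({"f": frozenset(["G0"])}))
        assert "f" not in xs.index


class TestHypergeometricBaseline:
    def test_matches_enumeration_oracle(self):
        universe = [f"G{i}" for i in range(100)]
        feature = frozenset(universe[:10])
        sig = set(universe[5:15])  # overlap 5
        net = FeatureNetwork({"f": feature})
        res = rp.hypergeometric_baseline(sig, universe, net)
        assert res.loc["f", "p_hyper"] == pytest.approx(
            oracles.hypergeom_tail(5, 100, 10, 10), abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"G{i}" for i in range(50)]
        net = FeatureNetwork({"f": frozenset(universe[:10])})
        res = rp.hypergeometric_baseline(set(universe[40:]), universe, net)
        assert res.loc["f", "p_hyper"] == pytest.approx(1.0)

    def test_feature_equal_to_universe_gives_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        net = FeatureNetwork({"f": frozenset(universe)})
        res = rp.hypergeometric_baseline(set(universe[:5]), universe, net)
        assert res.loc["f", "p_hyper"] == pytest.approx(1.0)

    def test_empty_significant_set_gives_all_p_one(self):
        universe = [f"G{i}" for i in range(50)]
        net = FeatureNetwork({"f": frozenset(universe[:10])})
        res = rp.hypergeometric_baseline(set(), universe, net)
        assert (res["p_hyper"] == 1.0).all()


class TestDirectionalZ:
    def test_down_side_flips_sign_of_up_genes(self):
        tab = pd.DataFrame({"t_stat": [-3.0, 3.0], "p_value": [0.02, 0.02]},
                           index=["down_gene", "up_gene"])
        z = rp.directional_z(tab, side="down")
        # one-tailed p = 0.01 for the matching gene, 0.99 for the opposite
        assert z["down_gene"] == pytest.approx(stats.norm.isf(0.01), abs=1e-9)
        assert z["up_gene"] == pytest.approx(stats.norm.isf(0.99), abs=1e-9)

    def test_sides_are_mirror_images(self):
        tab = pd.DataFrame({"t_stat": [-2.0, 1.0, 0.5], "p_value": [0.1, 0.4, 0.7]},
                           index=list("abc"))
        z_down = rp.directional_z(tab, side="down")
        z_up = rp.directional_z(tab, side="up")
        assert np.allclose(z_down.to_numpy(), -z_up.to_numpy(), atol=1e-9)
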