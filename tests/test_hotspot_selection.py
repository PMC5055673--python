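import numpy as np
import pandas as pd
import pytest

import phyloprior as pp
from phyloprior import hotspot_selection as hs

import _oracles as oracle


def make_table(f, raw, **extra):
    n = len(f)
    data = {
        "f_exp_pd_loss": f, "exp_pd_loss": raw,
        "f_sum_hedge": f, "sum_hedge": raw,
        "f_sum_bed": f, "sum_bed": raw,
        "n_top_hedge": extra.get("n_top", [0] * n),
        "n_top_bed": extra.get("n_top", [0] * n),
    }
    cells = extra.get("cells", [f"c{i:02d}" for i in range(n)])
    return pd.DataFrame(data, index=pd.Index(cells, name="cell"))


class TestRankCells:
    def test_f_primary_key(self):
        table = make_table([0.1, 0.9], [100.0, 1.0])
        assert pp.rank_cells(table, "exp_pdloss") == ["c01", "c00"]

    def test_raw_score_breaks_f_ties(self):
        table = make_table([0.5, 0.5], [5.0, 7.0])
        assert pp.rank_cells(table, "hedge") == ["c01", "c00"]

    def test_cell_id_breaks_full_ties(self):
        table = make_table([0.5, 0.5, 0.5], [1.0, 1.0, 1.0], cells=["z", "a", "m"])
        assert pp.rank_cells(table, "bed") == ["a", "m", "z"]


class TestSelectAichi:
    @pytest.mark.parametrize("n,expected", [(100, 17), (477, 81), (1489, 253)])
    def test_round_half_up_sizes(self, n, expected):
        ranked = [f"c{i}" for i in range(n)]
        sel = pp.select_aichi(ranked, 0.17)
        assert len(sel) == expected
        assert sel.cells == ranked[:expected]  # prefix of the ranking

    def test_zero_cell_selection_errors(self):
        with pytest.raises(ValueError, match="0 cells"):
            pp.select_aichi(["c1", "c2"], 0.1)


class TestSelectAlternative:
    def test_identical_cells_select_nothing_for_exp_pdloss(self):
        table = make_table([1.0, 1.0], [3.0, 3.0])
        sel = pp.select_alternative(table, "exp_pdloss")
        assert sel.cells == []  # nothing strictly above the mean

    def test_top_species_cell_selected_for_hedge(self):
        table = make_table([1.0, 0.0], [3.0, 1.0], n_top=[1, 0])
        sel = pp.select_alternative(table, "hedge")
        assert sel.cells == ["c00"]

    def test_alternative_may_exceed_aichi_size(self):
        # 10 cells, 9 hold a top species with F >= 0.5: selection > 17 %
        table = make_table(
            [0.9] * 10, list(range(10)), n_top=[1] * 9 + [0]
        )
        sel = hs.select_alternative(table, "bed")
        assert len(sel) == 9

    def test_f_threshold_is_inclusive_at_half(self):
        table = make_table([0.5, 0.49], [10.0, 10.0], n_top=[1, 1])
        assert hs.select_alternative(table, "hedge").cells == ["c00"]


class TestCaptureComplementarity:
    def test_all_cells_capture_everything_with_p_one(self, t1, t1_matrix, t1_probs):
        hset = hs.HotspotSet(index="exp_pdloss", rule="aichi_17", cells=["c1", "c2"])
        obs, p = pp.capture_complementarity(
            hset, "exp_pdloss", t1, t1_matrix, probs=t1_probs, n_rep=50, seed=0
        )
        assert obs == pytest.approx(100.0)
        assert p == 1.0  # every equal-size random set is the full set

    def test_duplicate_hotspots_union_idempotent(self, t1, t1_probs):
        frame = pd.DataFrame(
            {"A": [1, 1], "B": [1, 1], "C": [1, 1]},
            index=pd.Index(["c1", "c2"], name="cell"),
        )
        mat = pp.AssemblageMatrix(frame)
        one = hs.HotspotSet(index="", rule="aichi_17", cells=["c1"])
        two = hs.HotspotSet(index="", rule="aichi_17", cells=["c1", "c2"])
        o1, _ = pp.capture_complementarity(one, "exp_pdloss", t1, mat, probs=t1_probs,
                                           n_rep=10, seed=0)
        o2, _ = pp.capture_complementarity(two, "exp_pdloss", t1, mat, probs=t1_probs,
                                           n_rep=10, seed=0)
        assert o1 == pytest.approx(o2)

    def test_monotone_under_added_cells(self, t1, t1_matrix, t1_probs):
        small = hs.HotspotSet(index="", rule="aichi_17", cells=["c1"])
        large = hs.HotspotSet(index="", rule="aichi_17", cells=["c1", "c2"])
        o_small, _ = pp.capture_complementarity(
            small, "exp_pdloss", t1, t1_matrix, probs=t1_probs, n_rep=10, seed=0
        )
        o_large, _ = pp.capture_complementarity(
            large, "exp_pdloss", t1, t1_matrix, probs=t1_probs, n_rep=10, seed=0
        )
        assert o_large >= o_small

    def test_planted_fixture_full_capture_low_p(self):
        bundle = pp.planted_hotspot_scenario(seed=2)
        hedge_pool = sorted(
            pp.species_filter(bundle.species_table, "hedge") & set(bundle.tree.tips)
        )
        probs = bundle.species_table.loc[hedge_pool, "extinction_prob"]
        scores = pp.hed_hedge(bundle.tree.prune_to(hedge_pool), probs)["hedge"]
        hset = hs.HotspotSet(index="hedge", rule="aichi_17", cells=bundle.planted_cells)
        obs, p = pp.capture_complementarity(
            hset, "hedge", bundle.tree, bundle.matrix, scores=scores,
            n_rep=400, seed=3,
        )
        # clade species (the HEDGE mass) live only in planted cells
        assert obs > 99.0


class TestRichnessCorrelations:
    def test_monotone_and_reversed_pairs(self):
        table = pd.DataFrame(
            {
                "richness": [1, 2, 3, 4, 5],
                "threatened_richness": [5, 4, 3, 2, 1],
                "restricted_richness": [1, 2, 3, 4, 5],
                "exp_pd_loss": [1, 2, 3, 4, 5],
                "sum_hedge": [5.0, 4, 3, 2, 1],
                "sum_bed": [1.0, 2, 3, 4, 5],
            },
            index=pd.Index(list("abcde"), name="cell"),
        )
        pd_cell = pd.Series([1.0, 2, 3, 4, 5], index=table.index)
        out = pp.richness_correlations(table, pd_cell)
        assert out.loc[0, "rho"] == pytest.approx(1.0)     # richness vs PD
        assert out.loc[1, "rho"] == pytest.approx(-1.0)    # reversed pair

    def test_ties_match_brute_force_midrank_formula(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 5.0]
        table = pd.DataFrame(
            {
                "richness": x, "threatened_richness": x, "restricted_richness": x,
                "exp_pd_loss": y, "sum_hedge": y, "sum_bed": y,
            },
            index=pd.Index(list("abcde"), name="cell"),
        )
        out = pp.richness_correlations(table, pd.Series(y, index=table.index))
        want = oracle.spearman_brute(x, y)
        assert out.loc[1, "rho"] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_flagged(self):
        table = pd.DataFrame(
            {
                "richness": [1, 1, 1], "threatened_richness": [0, 1, 2],
                "restricted_richness": [0, 1, 2],
                "exp_pd_loss": [1.0, 2, 3], "sum_hedge": [1.0, 2, 3],
                "sum_bed": [1.0, 2, 3],
            },
            index=pd.Index(list("abc"), name="cell"),
        )
        out = pp.richness_correlations(table, pd.Series([1.0, 2, 3], index=table.index))
        assert bool(out.loc[0, "degenerate"]) is True
        assert np.isnan(out.loc[0, "rho"])


class TestPolytomySensitivity:
    @pytest.fixture
    def region(self):
        cfg = pp.ScenarioConfig(n_species=40, grid_shape=(6, 6), seed=5, dd_fraction=0.0)
        return pp.simulate_scenario(cfg)

    def _probs(self, bundle):
        pool = sorted(pp.species_filter(bundle.species_table, "hedge"))
        return bundle.species_table.loc[pool, "extinction_prob"]

    def test_zero_missing_species_rho_one(self, region):
        out = pp.polytomy_sensitivity(
            region.tree,
            missing=pd.DataFrame(columns=["genus"]),
            matrix=region.matrix,
            species_table=region.species_table,
            probs_by_species=self._probs(region),
            n_rep=5,
            seed=0,
        )
        for idx in ("exp_pdloss", "hedge", "bed"):
            assert np.allclose(out[idx], 1.0)

    def test_regrafting_keeps_rankings_stable(self, region):
        # drop two species from the tree and treat them as missing
        dropped = list(region.tree.tips)[:2]
        base = region.tree.prune_to([t for t in region.tree.tips if t not in dropped])
        missing = pd.DataFrame(
            {"genus": region.species_table.loc[dropped, "genus"]}, index=dropped
        )
        out = pp.polytomy_sensitivity(
            base,
            missing=missing,
            matrix=region.matrix,
            species_table=region.species_table,
            probs_by_species=self._probs(region),
            n_rep=6,
            seed=1,
        )
        for idx in ("exp_pdloss", "hedge", "bed"):
            assert np.median(out[idx]) >= 0.9

    def test_unknown_genus_errors(self, region):
        missing = pd.DataFrame({"genus": ["no_such_genus"]}, index=["ghost"])
        with pytest.raises(pp.PhylogenyError, match="absent"):
            pp.polytomy_sensitivity(
                region.tree, missing, region.matrix, region.species_table,
                self._probs(region), n_rep=2, seed=0,
            )
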