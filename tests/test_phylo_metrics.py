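import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phyloprior as pp
from phyloprior import phylo_metrics as pm

import _oracles as oracle
from conftest import T1, random_tree_and_probs

prob_triples = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=3, max_size=3
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(prob_triples)
def test_expected_loss_matches_enumeration_for_arbitrary_probabilities(ps):
    """Any probability vector (including exact 0/1) agrees with enumeration."""
    tree = pp.parse_newick(T1)
    probs = pd.Series(dict(zip("ABC", ps)))
    got = pp.expected_pd_loss(tree, probs, ["A", "B", "C"])
    want = oracle.expected_pd_loss_enum(T1, probs.to_dict(), ["A", "B", "C"])
    assert got == pytest.approx(want, abs=1e-12)
    assert 0.0 <= got <= pp.pd_subset(tree, ["A", "B", "C"]) + 1e-12


@settings(max_examples=60, deadline=None, derandomize=True)
@given(prob_triples)
def test_hedge_is_probability_times_hed(ps):
    tree = pp.parse_newick(T1)
    probs = pd.Series(dict(zip("ABC", ps)))
    hh = pp.hed_hedge(tree, probs)
    assert np.allclose(
        hh["hedge"].to_numpy(), probs.loc[hh.index].to_numpy() * hh["hed"].to_numpy()
    )


class TestCategoryMapping:
    def test_lookup(self):
        mapping = {"LC": 0.01, "NT": 0.02, "VU": 0.1, "EN": 0.5, "CR": 0.97}
        assert pp.category_to_probability("CR", mapping) == 0.97

    def test_non_monotone_mapping_rejected(self):
        bad = {"LC": 0.5, "NT": 0.02, "VU": 0.1, "EN": 0.5, "CR": 0.97}
        with pytest.raises(ValueError, match="increasing"):
            pp.category_to_probability("CR", bad)

    def test_default_preset_matches_shipped_file(self):
        preset = pp.default_probability_preset()
        # the shipped 50-year transformation of the Red List categories
        assert preset == {
            "LC": 0.00005,
            "NT": 0.004,
            "VU": 0.05,
            "EN": 0.42,
            "CR": 0.97,
        }
        vals = [preset[c] for c in ("LC", "NT", "VU", "EN", "CR")]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_unmapped_category_errors(self):
        with pytest.raises(KeyError, match="DD"):
            pp.category_to_probability("DD", pp.default_probability_preset())


class TestSpeciesFilter:
    @pytest.mark.parametrize(
        "index,expected",
        [("hedge", {"A"}), ("exp_pdloss", {"A"}), ("bed", {"A", "B"})],
    )
    def test_dd_rule_depends_on_index(self, index, expected):
        table = pd.DataFrame(
            {"iucn_category": ["LC", "DD", "EX"]}, index=["A", "B", "C"]
        )
        assert pp.species_filter(table, index) == expected

    def test_regionally_extinct_and_na_always_dropped(self):
        table = pd.DataFrame(
            {"iucn_category": ["RE", "NA", "CR"]}, index=["A", "B", "C"]
        )
        for index in ("hedge", "exp_pdloss", "bed"):
            assert pp.species_filter(table, index) == {"C"}

    def test_empty_table(self):
        table = pd.DataFrame({"iucn_category": []})
        assert pp.species_filter(table, "hedge") == set()


class TestFairProportionED:
    def test_t1_values(self, t1):
        ed = pp.fair_proportion_ed(t1)
        assert ed["A"] == pytest.approx(1.5)
        assert ed["B"] == pytest.approx(1.5)
        assert ed["C"] == pytest.approx(2.0)

    def test_star_tree_symmetry(self):
        tree = pp.parse_newick("(A:3,B:3,C:3,D:3);")
        ed = pp.fair_proportion_ed(tree)
        assert np.allclose(ed.to_numpy(), 3.0)

    def test_partition_identity_on_random_trees(self):
        rng = np.random.default_rng(20)
        for _ in range(100):
            tree, _ = random_tree_and_probs(rng, max_tips=40)
            ed = pp.fair_proportion_ed(tree)
            assert ed.sum() == pytest.approx(tree.total_branch_length, abs=1e-9)

    def test_matches_picante_evol_distinct(self, tmp_path):
        """Cross-check fair-proportion ED against R picante on one tree."""
        import subprocess

        tree = pp.simulate_tree(12, seed=99)
        nwk = tmp_path / "t.nwk"
        nwk.write_text(tree.to_newick() + "\n")
        script = (
            f'library(picante); t <- read.tree("{nwk}");'
            'r <- evol.distinct(t, type="fair.proportion");'
            'write.csv(r, stdout(), row.names=FALSE)'
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", "-e", script],
            capture_output=True, text=True, timeout=120, check=True,
        )
        lines = [l for l in out.stdout.splitlines() if "," in l and "Species" not in l]
        r_ed = {l.split(",")[0].strip('"'): float(l.split(",")[1]) for l in lines}
        ed = pp.fair_proportion_ed(tree)
        for sp, val in r_ed.items():
            assert ed[sp] == pytest.approx(val, rel=1e-6)


class TestExpectedPDLoss:
    def test_certain_and_impossible_loss(self, t1):
        ones = pd.Series(1.0, index=["A", "B", "C"])
        zeros = pd.Series(0.0, index=["A", "B", "C"])
        assert pp.expected_pd_loss(t1, ones, ["A", "B", "C"]) == pytest.approx(5.0)
        assert pp.expected_pd_loss(t1, zeros, ["A", "B", "C"]) == pytest.approx(0.0)

    def test_t1_enumeration_value(self, t1, t1_probs):
        # frozen from the 2^3 outcome enumeration oracle
        expected = oracle.expected_pd_loss_enum(
            T1, t1_probs.to_dict(), ["A", "B", "C"]
        )
        assert expected == pytest.approx(1.45)
        got = pp.expected_pd_loss(t1, t1_probs, ["A", "B", "C"])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_on_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            tree, probs = random_tree_and_probs(rng, max_tips=10)
            sub = sorted(
                rng.choice(tree.tips, size=rng.integers(1, tree.n_tips + 1), replace=False)
            )
            got = pp.expected_pd_loss(tree, probs, sub)
            want = oracle.expected_pd_loss_enum(tree.to_newick(), probs.to_dict(), sub)
            assert got == pytest.approx(want, abs=1e-10)

    def test_monotone_in_each_probability(self, t1, t1_probs):
        base = pp.expected_pd_loss(t1, t1_probs, ["A", "B", "C"])
        for sp in t1.tips:
            bumped = t1_probs.copy()
            bumped[sp] = min(1.0, bumped[sp] + 0.2)
            assert pp.expected_pd_loss(t1, bumped, ["A", "B", "C"]) >= base

    def test_complementarity_bounds_with_equal_p(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tree, _ = random_tree_and_probs(rng, max_tips=15)
            p = float(rng.uniform(0.05, 0.95))
            probs = pd.Series(p, index=list(tree.tips))
            loss = pp.expected_pd_loss(tree, probs, list(tree.tips))
            total = tree.total_branch_length
            assert p**tree.n_tips * total - 1e-9 <= loss <= p * total + 1e-9

    def test_missing_probability_names_species(self, t1):
        probs = pd.Series({"A": 0.5, "B": 0.5})
        with pytest.raises(ValueError, match="C"):
            pp.expected_pd_loss(t1, probs, ["A", "B", "C"])

    def test_subset_mrca_rooting_excludes_stem(self, t1):
        probs = pd.Series({"A": 0.5, "B": 0.5, "C": 0.1})
        # {A,B}: regional rooting includes the stem branch secured only by A,B
        reg = pp.expected_pd_loss(t1, probs, ["A", "B"], rooting="regional_root")
        mrca = pp.expected_pd_loss(t1, probs, ["A", "B"], rooting="subset_mrca")
        assert reg == pytest.approx(mrca + 1.0 * 0.25)


class TestHedHedge:
    def test_certain_sibling_secures_shared_branch(self, t1):
        probs = pd.Series({"A": 0.5, "B": 1.0, "C": 0.1})
        hh = pp.hed_hedge(t1, probs)
        assert hh.loc["A", "hed"] == pytest.approx(2.0)

    def test_t1_values_and_hedge_identity(self, t1, t1_probs):
        hh = pp.hed_hedge(t1, t1_probs)
        assert hh.loc["A", "hed"] == pytest.approx(1.5)
        assert hh.loc["A", "hedge"] == pytest.approx(0.75)
        assert np.allclose(
            hh["hedge"].to_numpy(),
            t1_probs.loc[hh.index].to_numpy() * hh["hed"].to_numpy(),
        )

    def test_all_zero_probs_leave_terminal_branch(self, t1):
        probs = pd.Series(0.0, index=["A", "B", "C"])
        hh = pp.hed_hedge(t1, probs)
        for tip in t1.tips:
            # only the terminal branch is at risk when relatives are safe
            bt = t1.branch_table()
            i = bt.tip_index[tip]
            term = bt.lengths[(bt.memb.sum(axis=1) == 1) & bt.memb[:, i]][0]
            assert hh.loc[tip, "hed"] == pytest.approx(term)

    def test_matches_conditional_expectation_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            tree, probs = random_tree_and_probs(rng, max_tips=10)
            got = pp.hed_hedge(tree, probs)["hed"]
            want = oracle.hed_enum(tree.to_newick(), probs.to_dict())
            for sp in tree.tips:
                assert got[sp] == pytest.approx(want[sp], abs=1e-10)

    def test_hed_bounded_by_terminal_and_root_path(self):
        rng = np.random.default_rng(23)
        tree, probs = random_tree_and_probs(rng, max_tips=12)
        hh = pp.hed_hedge(tree, probs)
        bt = tree.branch_table()
        for i, sp in enumerate(bt.tips):
            term = bt.lengths[(bt.memb.sum(axis=1) == 1) & bt.memb[:, i]][0]
            assert term - 1e-12 <= hh.loc[sp, "hed"] <= tree.distance_to_root(sp) + 1e-12


class TestBED:
    def test_single_cell_universe_gives_root_to_tip(self, t1):
        frame = pd.DataFrame(
            {"A": [1], "B": [1], "C": [1]}, index=pd.Index(["c1"], name="cell")
        )
        scores = pp.bed(t1, pp.AssemblageMatrix(frame))
        for sp in t1.tips:
            assert scores[sp] == pytest.approx(t1.distance_to_root(sp))

    def test_t1_union_ranges(self, t1, t1_matrix):
        scores = pp.bed(t1, t1_matrix)
        # A: terminal branch /1 + shared AB branch /1 (both confined to c1)
        assert scores["A"] == pytest.approx(2.0)
        want = oracle.bed_union_brute(
            t1.to_newick(), {"A": {"c1"}, "B": {"c1"}, "C": {"c2"}}
        )
        for sp in t1.tips:
            assert scores[sp] == pytest.approx(want[sp])

    def test_matches_union_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(31)
        tree = pp.simulate_tree(10, seed=4)
        sizes = rng.integers(1, 12, size=10)
        matrix = pp.simulate_ranges((4, 4), sizes, seed=9, species_labels=list(tree.tips))
        ranges = {
            sp: set(matrix.frame.index[matrix.frame[sp] > 0]) for sp in tree.tips
        }
        got = pp.bed(tree, matrix)
        want = oracle.bed_union_brute(tree.to_newick(), ranges)
        for sp in tree.tips:
            assert got[sp] == pytest.approx(want[sp])

    def test_cell_duplication_halves_scores(self, t1, t1_matrix):
        doubled = pd.concat(
            [t1_matrix.frame,
             t1_matrix.frame.set_axis(["c1b", "c2b"], axis=0)]
        )
        scores = pp.bed(t1, pp.AssemblageMatrix(doubled))
        base = pp.bed(t1, t1_matrix)
        assert np.allclose(scores.to_numpy(), base.to_numpy() / 2.0)

    def test_occurrence_sum_variant_partitions_branches(self, t1, t1_matrix):
        scores = pp.bed(t1, t1_matrix, variant="occurrence_sum")
        # A: 1·(1/1)... terminal r_A/r_A + shared branch r_A/(r_A+r_B)
        assert scores["A"] == pytest.approx(1.0 + 0.5)
        assert scores["C"] == pytest.approx(2.0)

    def test_empty_range_errors(self, t1):
        frame = pd.DataFrame(
            {"A": [1], "B": [1], "C": [0]}, index=pd.Index(["c1"], name="cell")
        )
        matrix = pp.AssemblageMatrix(frame, drop_empty_species=False)
        with pytest.raises(ValueError, match="empty range"):
            pp.bed(t1, matrix)
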