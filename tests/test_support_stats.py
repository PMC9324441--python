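import numpy as np
import pytest

from retroquartet import (
    pcs, removal_index, bootstrap, linked_support_report,
    exhaustive_search, tree_has_clade, quartet_score,
)
from retroquartet.support_stats import _tree_splits
from retroquartet._unrooted import UTree
from util import split_locus, random_split_locus


class TestPCS:
    def test_worked_example(self):
        """Locus {A,B}|{C,D,E}: agreement 3 with ((A,B),(C,(D,E))) and 1
        with ((A,C),(B,(D,E))) -> pcs = 2."""
        locus = split_locus(1, "AB", "CDE")
        table = pcs([locus], "((A,B),(C,(D,E)));", ["A", "B"],
                    anti="((A,C),(B,(D,E)));")
        assert table.table["pcs"].iloc[0] == 2
        assert table.coalescence_support == 2

    def test_indifferent_locus_scores_zero(self):
        locus = split_locus(1, "DE", "ABC")  # same agreement in both trees
        table = pcs([locus], "((A,B),(C,(D,E)));", ["A", "B"],
                    anti="((A,C),(B,(D,E)));")
        assert table.table["pcs"].iloc[0] == 0

    def test_conservation_random_fixtures(self, rng):
        labels = list("abcdef")
        for trial in range(8):
            loci = [random_split_locus(rng, labels, i) for i in range(12)]
            opt = exhaustive_search(loci, labels)
            clade = sorted(_tree_splits(opt.tree)[0])
            table = pcs(loci, opt, clade)
            assert table.table["pcs"].sum() == pytest.approx(
                table.optimal_score - table.anti_score)
            assert table.coalescence_support == pytest.approx(
                quartet_score(opt.tree, loci)
                - quartet_score(table.anti_tree, loci))

    def test_absent_clade_errors(self):
        locus = split_locus(1, "AB", "CDE")
        with pytest.raises(ValueError, match="absent"):
            pcs([locus], "((A,B),(C,(D,E)));", ["A", "C"])


class TestRemovalIndex:
    def test_single_clean_locus(self):
        # clade {A,B} held up by one clean locus over a neutral background
        loci = [split_locus(1, "AB", "CDE"),
                split_locus(2, "DE", "ABC"), split_locus(3, "DE", "ABC")]
        res = removal_index(loci, ["A", "B"])
        assert res.index == 1
        assert res.removed_locus_ids == [1]
        assert res.is_upper_bound

    def test_house_of_cards_joint_removal(self, house_of_cards_loci):
        """Two jointly-determining loci: index 2, and the removed loci
        conflict with clades that collapse alongside the focal one."""
        loci = house_of_cards_loci
        opt = exhaustive_search(loci, list("abcdef"))
        assert not opt.tie
        assert tree_has_clade(opt.tree, ["c", "d"])
        res = removal_index(loci, ["c", "d"])
        assert res.index == 2
        assert sorted(res.removed_locus_ids) == [1, 5]  # acd|bef, aef|bcd
        remaining = [l for l in loci
                     if l.locus_id not in set(res.removed_locus_ids)]
        post = exhaustive_search(remaining, list("abcdef"))
        collapsed = [c for c in _tree_splits(opt.tree)
                     if not tree_has_clade(post.tree, c)]
        assert frozenset(["c", "d"]) in collapsed
        assert len(collapsed) >= 2  # linked collapse

        def conflicts(side, clade):
            s, c, t = set(side), set(clade), set("abcdef")
            return all(x & y for x in (s, t - s) for y in (c, t - c))

        for lid, side in [(1, "acd"), (5, "aef")]:
            assert any(conflicts(side, c) for c in collapsed)

    def test_unbounded_when_support_uniform(self):
        loci = [split_locus(i, "AB", "CDE") for i in range(30)]
        res = removal_index(loci, ["A", "B"], max_removals=5)
        assert res.unbounded and res.index is None

    def test_positive_support_implies_index_at_least_one(self, rng):
        labels = list("abcde")
        loci = [random_split_locus(rng, labels, i) for i in range(10)]
        opt = exhaustive_search(loci, labels)
        for clade in _tree_splits(opt.tree):
            table = pcs(loci, opt, sorted(clade))
            if table.coalescence_support > 0:
                res = removal_index(loci, sorted(clade), max_removals=10)
                assert res.unbounded or res.index >= 1


class TestBootstrap:
    def test_identical_loci_give_full_support(self):
        tree = UTree.from_newick("((A,B),((C,D),E));")
        loci = ([split_locus(i, "AB", "CDE") for i in range(6)]
                + [split_locus(10 + i, "CD", "ABE") for i in range(6)])
        res = bootstrap(loci, n_replicates=20, seed=3)
        for clade, pct in res.percentages.items():
            assert pct == 100.0

    def test_determinism(self, rng):
        labels = list("abcde")
        loci = [random_split_locus(rng, labels, i) for i in range(10)]
        r1 = bootstrap(loci, n_replicates=5, seed=11)
        r2 = bootstrap(loci, n_replicates=5, seed=11)
        assert r1.percentages == r2.percentages

    def test_support_nondecreasing_in_clean_loci(self):
        """Adding clean supporting loci to a fixed conflicted background
        never lowers a clade's bootstrap percentage."""
        background = [split_locus(100 + i, s, r) for i, (s, r) in
                      enumerate([("AC", "BDE"), ("BD", "ACE"),
                                 ("AD", "BCE"), ("DE", "ABC")])]
        pcts = []
        for extra in (2, 5, 9):
            loci = background + [split_locus(i, "AB", "CDE")
                                 for i in range(extra)]
            res = bootstrap(loci, n_replicates=30, seed=1,
                            reference="((A,B),(C,(D,E)));")
            pcts.append(res.percent(["A", "B"]))
        assert pcts == sorted(pcts)


class TestLinkedSupport:
    def test_empty_clade_list(self, house_of_cards_loci):
        opt = exhaustive_search(house_of_cards_loci, list("abcdef"))
        rep = linked_support_report(house_of_cards_loci, opt, [])
        assert rep.anti_losses == {} and rep.removal_losses == []

    def test_anticonstraint_linked_losses(self):
        """Star-like conflicted data: the best tree lacking one clade
        also contradicts two more optimal-tree clades (interdependent
        support; fixture found by exhaustive search)."""
        taxa = set("abcdef")
        sides = [(1, "de"), (2, "de"), (3, "bf"), (4, "df"), (5, "df"),
                 (6, "ae"), (7, "ade"), (8, "ade")]
        loci = [split_locus(i, sorted(s), sorted(taxa - set(s)))
                for i, s in sides]
        opt = exhaustive_search(loci, sorted(taxa))
        assert not opt.tie
        rep = linked_support_report(loci, opt, [["b", "c", "f"]])
        lost = rep.anti_losses[frozenset(["b", "c", "f"])]
        assert {frozenset(c) for c in lost} >= {frozenset("de"),
                                                frozenset("bf")}

    def test_independent_clade_loses_only_itself(self):
        tree = UTree.from_newick("((A,B),((C,D),(E,F)));")
        loci = []
        k = 0
        for side, rest in [("AB", "CDEF"), ("CD", "ABEF"), ("EF", "ABCD")]:
            for _ in range(6):
                k += 1
                loci.append(split_locus(k, side, rest))
        opt = exhaustive_search(loci, list("ABCDEF"))
        rep = linked_support_report(loci, opt, [["A", "B"]])
        assert rep.anti_losses[frozenset(["A", "B"])] == []

    def test_joint_removal_collapse(self, house_of_cards_loci):
        loci = house_of_cards_loci
        opt = exhaustive_search(loci, list("abcdef"))
        rep = linked_support_report(loci, opt, [], removal_sets=[[1, 5]])
        (removed, collapsed), = rep.removal_losses
        assert removed == [1, 5]
        assert frozenset(["c", "d"]) in collapsed
        assert len(collapsed) >= 3
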