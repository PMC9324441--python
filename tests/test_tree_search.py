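import numpy as np
import pytest

from retroquartet import (
    RIMatrix, TaxonSet, exhaustive_search, hillclimb_search,
    anticonstraint_search, sdp_quartets, build_mrp_matrix, mrp_treelength,
    tree_has_clade, quartet_score,
)
from retroquartet.tree_search import EXHAUSTIVE_MAX_TAXA
from retroquartet._unrooted import UTree, enumerate_topologies, taxon_index
from retroquartet.synthetic_data import SimulationConfig, simulate_ri_matrix
from retroquartet.rimatrix import to_bipartitions
from retroquartet.quartet_engine import locus_from_bipartition
from util import split_locus, random_split_locus


def perfect_loci(tree: UTree, copies: int = 2):
    """Loci identical to every split of the tree."""
    idx = taxon_index(tree.leaf_labels())
    inv = {i: l for l, i in idx.items()}
    loci = []
    k = 0
    for mask in tree.split_masks(idx).values():
        side = [inv[i] for i in range(len(inv)) if mask >> i & 1]
        rest = [l for l in tree.leaf_labels() if l not in side]
        for _ in range(copies):
            k += 1
            loci.append(split_locus(k, side, rest))
    return loci


class TestExhaustive:
    def test_topology_counts(self):
        assert sum(1 for _ in enumerate_topologies(list("abcde"))) == 15
        assert sum(1 for _ in enumerate_topologies(list("abcdef"))) == 105

    def test_perfect_data_recovers_tree(self):
        true = UTree.from_newick("((A,B),((C,D),(E,F)));")
        res = exhaustive_search(perfect_loci(true), true.leaf_labels())
        assert res.newick == true.canonical_newick()
        assert not res.tie
        assert res.score == quartet_score(true, perfect_loci(true))

    def test_majority_wins(self):
        loci = [split_locus(1, "AB", "CD"), split_locus(2, "AB", "CD"),
                split_locus(3, "AC", "BD")]
        res = exhaustive_search(loci, list("ABCD"))
        assert tree_has_clade(res.tree, ["A", "B"])
        assert res.score == 2

    def test_tie_flagged_with_canonical_winner(self):
        loci = [split_locus(1, "AB", "CD"), split_locus(2, "AC", "BD")]
        res = exhaustive_search(loci, list("ABCD"))
        assert res.tie
        assert res.newick == min(res.co_optimal)
        assert len(res.co_optimal) == 2

    def test_taxon_cap(self):
        labels = [chr(97 + i) for i in range(EXHAUSTIVE_MAX_TAXA + 1)]
        with pytest.raises(ValueError):
            exhaustive_search([], labels)


class TestHillclimb:
    def test_determinism(self, rng):
        labels = list("abcdefgh")
        loci = [random_split_locus(rng, labels, i) for i in range(20)]
        r1 = hillclimb_search(loci, labels, restarts=1, seed=5)
        r2 = hillclimb_search(loci, labels, restarts=1, seed=5)
        assert r1.newick == r2.newick and r1.score == r2.score

    def test_never_beats_exhaustive_often_matches(self, rng):
        """20-restart NNI matches the exact optimum on >= 95% of random
        7-taxon instances and never exceeds it (smaller sweep; the
        acceptance suite runs the full comparison)."""
        labels = list("abcdefg")
        matches = 0
        trials = 25
        for t in range(trials):
            loci = [random_split_locus(rng, labels, i) for i in range(12)]
            exact = exhaustive_search(loci, labels)
            heur = hillclimb_search(loci, labels, restarts=20, seed=t)
            assert heur.score <= exact.score
            matches += heur.score == exact.score
        assert matches / trials >= 0.95

    def test_perfect_data_twenty_taxa(self, rng):
        labels = [chr(97 + i) for i in range(20)]
        true = UTree.random_topology(labels, np.random.default_rng(3))
        loci = perfect_loci(true, copies=1)
        res = hillclimb_search(loci, labels, restarts=8, seed=11,
                               candidate_pool=None)
        assert res.newick == true.canonical_newick()

    def test_candidate_pool_used_as_start(self):
        true = UTree.from_newick("((A,B),((C,D),(E,F)));")
        loci = perfect_loci(true)
        res = hillclimb_search(loci, true.leaf_labels(), restarts=1, seed=0,
                               candidate_pool=[true])
        assert res.newick == true.canonical_newick()


class TestAnticonstraint:
    def test_forbidden_clade_excluded(self):
        loci = [split_locus(i, "AB", "CD") for i in range(3)]
        res = anticonstraint_search(loci, list("ABCD"), ["A", "B"])
        assert not tree_has_clade(res.tree, ["A", "B"])
        assert res.score == 0
        assert res.tie

    def test_noop_when_clade_not_optimal(self, rng):
        labels = list("abcdef")
        loci = [random_split_locus(rng, labels, i) for i in range(10)]
        unconstrained = exhaustive_search(loci, labels)
        # forbid a clade absent from the optimum
        from retroquartet.support_stats import _tree_splits
        all_pairs = [frozenset(p) for p in
                     [("a", "b"), ("a", "c"), ("a", "d"), ("a", "e")]]
        absent = next(c for c in all_pairs
                      if not tree_has_clade(unconstrained.tree, c))
        res = anticonstraint_search(loci, labels, absent)
        assert res.score == unconstrained.score

    def test_forbidding_true_clade_costs_score(self, rng):
        true = UTree.from_newick("(((a,b),c),((d,e),f));")
        m, _ = simulate_ri_matrix(SimulationConfig(
            species_tree="(((a:1,b:1):1,c:2):1,((d:1,e:1):1,f:2):1);",
            n_characters=300, placement="internal", seed=4))
        loci = [locus_from_bipartition(b) for b in to_bipartitions(m, 2)]
        unconstrained = exhaustive_search(loci, list("abcdef"))
        assert tree_has_clade(unconstrained.tree, ["a", "b"])
        res = anticonstraint_search(loci, list("abcdef"), ["a", "b"])
        assert res.score < unconstrained.score

    def test_trivial_forbidden_clade_errors(self):
        with pytest.raises(ValueError):
            anticonstraint_search([], list("ABCD"), ["A"])


class TestSDPQuartets:
    def test_four_taxon_parsimony(self):
        m = RIMatrix(TaxonSet(tuple("ABCD")),
                     np.array([[1, 1], [1, 1], [0, 0], [0, 0]]))
        res = sdp_quartets(m)
        assert tree_has_clade(res.tree, ["A", "B"])
        mrp = res.extras["mrp"]
        assert len(mrp) == 1 and res.extras["mrp_treelength"] == 1

    def test_tie_encodes_both_rows(self):
        m = RIMatrix(TaxonSet(tuple("ABCD")),
                     np.array([[1, 1], [1, 0], [0, 1], [0, 0]]))
        mrp = build_mrp_matrix(m)
        assert len(mrp.rows) == 2
        assert {r.pair for r in mrp.rows} == {("A", "B"), ("A", "C")}

    def test_clean_simulation_recovers_tree_and_treelength(self):
        true = "((((a:1,b:1):2,c:3):2,d:5):2,(e:1,f:1):6);"
        m, _ = simulate_ri_matrix(SimulationConfig(
            species_tree=true, n_characters=400, placement="internal",
            seed=9))
        res = sdp_quartets(m)
        want = UTree.from_newick("((((a,b),c),d),(e,f));")
        assert res.newick == want.canonical_newick()
        mrp = res.extras["mrp"]
        # long internodes: every quartet row should fit in one step
        assert res.extras["mrp_treelength"] == len(mrp)
        assert res.extras["mrp_treelength"] == mrp_treelength(mrp, res.tree)

    def test_backbone_constraint_respected(self, rng):
        labels = list("abcdef")
        loci_m, _ = simulate_ri_matrix(SimulationConfig(
            species_tree="(((a:1,b:1):1,c:2):1,((d:1,e:1):1,f:2):1);",
            n_characters=150, placement="internal", seed=2))
        backbone = "((a,c),(d,f));"
        res = sdp_quartets(loci_m, backbone_constraint=None, seed=1,
                           exhaustive=False, restarts=6)
        res_bb = sdp_quartets(loci_m, backbone_constraint=backbone, seed=1,
                              exhaustive=False, restarts=6)
        from retroquartet.tree_search import _displays_backbone
        idx = taxon_index(labels)
        assert _displays_backbone(res_bb.tree, UTree.from_newick(backbone),
                                  idx)
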