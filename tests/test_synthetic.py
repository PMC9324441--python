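import math

import numpy as np
import pytest

from retroquartet import (
    SimulationConfig, Reticulation, simulate_msc_gene_tree,
    simulate_ri_matrix, simulate_support_gene_trees, missing_summary,
    to_bipartitions, locus_from_bipartition, exhaustive_search,
    collapse_low_support, read_gene_trees, InputLocus,
    AVIAN48_MISSING_COUNTS, AVIAN48_N_CHARACTERS,
)
from retroquartet._unrooted import UTree
from retroquartet.synthetic_data import (_parse_species_tree, _simulate_one,
                                         _find_branch, _MSCSimulator)


def pairing_fraction(nwk, n, seed, want={"A", "B"}):
    root, _ = _parse_species_tree(nwk)
    sim = _MSCSimulator(root, None, None, None)
    rng = np.random.default_rng(seed)
    hit = 0
    for _ in range(n):
        g = sim.run(rng)
        for c in g.root.children:
            if len(c.tipset) == 2:
                hit += c.tipset == frozenset(want)
    return hit / n


class TestGeneTreeSimulation:
    def test_star_symmetry_at_zero_length(self):
        frac = pairing_fraction("((A:1,B:1):0,C:1);", 12000, 1)
        se = math.sqrt((1 / 3) * (2 / 3) / 12000)
        assert abs(frac - 1 / 3) < 3 * se

    @pytest.mark.parametrize("t", [0.1, 0.5])
    def test_matches_msc_closed_form(self, t):
        n = 12000
        frac = pairing_fraction("((A:1,B:1):%g,C:%g);" % (t, 1 + t), n, 2)
        expect = 1 - (2 / 3) * math.exp(-t)
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(frac - expect) < 3 * se

    def test_determinism_given_seed(self):
        cfg = SimulationConfig(species_tree="((A:1,B:1):1,C:2);", seed=9)
        g1 = simulate_msc_gene_tree(cfg)
        g2 = simulate_msc_gene_tree(cfg)
        assert g1.newick() == g2.newick()

    def test_gamma_one_follows_donor(self):
        """With gamma = 1 every recipient lineage crosses to the donor:
        the pairing follows the donor displayed tree."""
        nwk = "((A:1,B:1):1,C:2);"
        ret = Reticulation(donor=("C",), recipient=("B",), time=0.5,
                           gamma=1.0)
        root, _ = _parse_species_tree(nwk)
        d = _find_branch(root, frozenset(["C"]))
        r = _find_branch(root, frozenset(["B"]))
        sim = _MSCSimulator(root, ret, d, r)
        rng = np.random.default_rng(11)
        n, hit = 8000, 0
        for _ in range(n):
            g = sim.run(rng)
            for c in g.root.children:
                if len(c.tipset) == 2:
                    hit += c.tipset == frozenset({"B", "C"})
        # B sits in the C branch from 0.5 to the root at 2: 1.5 CU
        expect = (1 - math.exp(-1.5)) + math.exp(-1.5) / 3
        se = math.sqrt(expect * (1 - expect) / n)
        assert abs(hit / n - expect) < 3 * se

    def test_reticulation_time_outside_branch_errors(self):
        cfg = SimulationConfig(
            species_tree="((A:1,B:1):1,C:2);",
            reticulation=Reticulation(donor=("C",), recipient=("B",),
                                      time=1.5, gamma=0.3))
        with pytest.raises(ValueError, match="outside"):
            simulate_msc_gene_tree(cfg)

    def test_non_ultrametric_tree_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            simulate_msc_gene_tree(
                SimulationConfig(species_tree="((A:1,B:2):1,C:2);"))


class TestRIMatrixSimulation:
    def test_internal_placement_four_taxa_all_informative(self):
        cfg = SimulationConfig(
            species_tree="((A:1,B:1):0.5,(C:1,D:1):0.5);",
            n_characters=150, placement="internal", seed=5)
        m, truth = simulate_ri_matrix(cfg)
        bps = to_bipartitions(m, min_side=2)
        assert len(bps) == 150
        assert len(truth) == 150

    def test_truth_presence_sets_match_matrix(self):
        cfg = SimulationConfig(
            species_tree="(((a:1,b:1):1,c:2):1,d:3);",
            n_characters=60, placement="any", seed=8)
        m, truth = simulate_ri_matrix(cfg)
        for j, rec in enumerate(truth):
            col = m.states[:, j]
            present = {m.taxa.labels[i] for i in np.flatnonzero(col == 1)}
            assert present == set(rec.insertion_clade)

    def test_masking_matches_target_rate(self):
        cfg = SimulationConfig(
            species_tree="((A:1,B:1):0.5,(C:1,D:1):0.5);",
            n_characters=2500, placement="any", missing_rates=0.28, seed=6)
        m, _ = simulate_ri_matrix(cfg)
        frac = missing_summary(m).fraction
        se = math.sqrt(0.28 * 0.72 / (2500 * 4))
        assert abs(frac - 0.28) < 3 * se

    def test_avian_preset_reproduces_published_profile(self):
        assert len(AVIAN48_MISSING_COUNTS) == 48
        mean = sum(AVIAN48_MISSING_COUNTS.values()) / 48
        assert round(mean) == 600
        assert round(100 * mean / AVIAN48_N_CHARACTERS) == 28

    def test_informative_only_unattainable_errors(self):
        cfg = SimulationConfig(species_tree="((A:1,B:1):0.2,C:1.2);",
                               n_characters=5, placement="internal", seed=1)
        with pytest.raises(RuntimeError, match="informative"):
            simulate_ri_matrix(cfg)  # 3 taxa: no 2v1+ split exists


class TestSupportGeneTrees:
    def test_zero_trees_empty_list(self):
        cfg = SimulationConfig(species_tree="((A:1,B:1):1,C:2);", seed=1)
        assert simulate_support_gene_trees(cfg, 0) == []

    def test_error_free_trees_have_high_labels(self):
        cfg = SimulationConfig(
            species_tree="(((a:1,b:1):2,c:3):2,d:5);", seed=2)
        trees = simulate_support_gene_trees(cfg, 10, error_rate=0.0)
        loci = [InputLocus(i, UTree.from_newick(t))
                for i, t in enumerate(trees)]
        for l in loci:
            assert all(s >= 80 for s in l.tree.esup.values())
        # collapse-at-50 leaves error-free trees untouched
        for l in loci:
            c = collapse_low_support(l, 49)
            assert len(c.tree.internal_edges()) == \
                len(l.tree.internal_edges())

    def test_weighting_rescues_noisy_short_internodes(self):
        """With heavy reconstruction error on gene trees, collapsing
        low-support nodes before the combined search recovers the
        generating topology at least as often as equal weighting."""
        true_nwk = "(((a:1,b:1):0.4,c:1.4):0.4,(d:1,e:1):0.8);"
        true = UTree.from_newick("(((a,b),c),(d,e));")
        taxa = sorted(true.leaf_labels())
        wins_collapsed = wins_equal = 0
        for rep in range(12):
            cfg = SimulationConfig(species_tree=true_nwk, seed=300 + rep)
            rng = np.random.default_rng(300 + rep)
            trees = simulate_support_gene_trees(cfg, 24, error_rate=0.5,
                                                rng=rng)
            loci = [InputLocus(i, UTree.from_newick(t))
                    for i, t in enumerate(trees)]
            equal = exhaustive_search(loci, taxa)
            collapsed = [collapse_low_support(l, 49) for l in loci]
            coll = exhaustive_search(collapsed, taxa)
            wins_equal += equal.newick == true.canonical_newick()
            wins_collapsed += coll.newick == true.canonical_newick()
        assert wins_collapsed >= wins_equal
        assert wins_collapsed >= 6  # the filtered search mostly succeeds
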