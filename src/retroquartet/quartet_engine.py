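"""Quartet agreement between species trees and input loci.

The objective of the whole pipeline: for a candidate species tree and a
set of input loci (single-bipartition "gene trees" from RI characters, or
ordinary multi-edge gene trees), count, over every four-leaf subset that a
locus resolves, whether the locus-induced quartet matches the quartet the
species tree induces.  Counting is exact and combinatorial (bitmask
intersection counts over the species tree's internal-vertex pairs for
bipartition loci; explicit four-subset classification for multi-edge
loci); no quartet sampling anywhere.

Weighted mode follows the support-weighting idea of weighted-ASTRAL-style
analyses: the weight of an induced quartet is the minimum support on the
locus-tree edges separating its two cherries (which reduces to the single
edge support for a bipartition locus, and 100 for RI bipartitions by
convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import dendropy

from ._unrooted import UTree, taxon_index, quartet_pairing

TreeLike = Union[UTree, str, "dendropy.Tree"]

DEFAULT_EDGE_WEIGHT = 100.0   # unannotated edges are treated as fully trusted


def as_utree(tree: TreeLike) -> UTree:
    if isinstance(tree, UTree):
        return tree
    if isinstance(tree, str):
        return UTree.from_newick(tree)
    if isinstance(tree, dendropy.Tree):
        return UTree.from_dendropy(tree)
    raise TypeError("cannot interpret %r as a tree" % (tree,))


@dataclass
class InputLocus:
    """One input locus: an unrooted leaf-labeled tree with optional
    per-internal-edge support weights in [0, 100]."""

    locus_id: Union[int, str]
    tree: UTree

    def __post_init__(self):
        for e, s in self.tree.esup.items():
            if not (0.0 <= s <= 100.0):
                raise ValueError(
                    "support %g outside [0,100] on locus %r" % (s, self.locus_id))

    @property
    def leaf_labels(self) -> List[str]:
        return self.tree.leaf_labels()

    def is_bipartition(self) -> bool:
        return len(self.tree.internal_edges()) == 1

    def split_sides(self) -> Optional[Tuple[frozenset, frozenset]]:
        if not self.is_bipartition():
            return None
        index = taxon_index(self.leaf_labels)
        (edge, mask), = self.tree.split_masks(index).items()
        inv = {i: lab for lab, i in index.items()}
        side = frozenset(inv[i] for i in range(len(inv)) if mask >> i & 1)
        other = frozenset(self.leaf_labels) - side
        return side, other

    def edge_weight(self) -> float:
        """Support of the single internal edge of a bipartition locus."""
        edges = self.tree.internal_edges()
        if len(edges) != 1:
            raise ValueError("edge_weight is defined for bipartition loci only")
        return self.tree.esup.get(
            (min(edges[0]), max(edges[0])), DEFAULT_EDGE_WEIGHT)


def locus_from_bipartition(bp, support: float = 100.0) -> InputLocus:
    """An RI bipartition as a single-split gene tree (max weight by the
    convention that RIs are as reliable as a 100%-bootstrap node)."""
    tree = UTree.from_split(sorted(bp.side_present), sorted(bp.side_absent))
    edges = tree.internal_edges()
    if edges:   # a 1-vs-N character has none and resolves no quartets
        (u, v), = edges
        tree.esup[(min(u, v), max(u, v))] = support
    return InputLocus(locus_id=bp.locus_id, tree=tree)


def loci_from_bipartitions(bps, support: float = 100.0) -> List[InputLocus]:
    return [locus_from_bipartition(bp, support) for bp in bps]


def read_gene_trees(path: str, id_prefix: str = "gt") -> List[InputLocus]:
    """Newick gene trees; internal-node labels are read as supports on the
    subtending edge."""
    trees = dendropy.TreeList.get(path=path, schema="newick",
                                  suppress_internal_node_taxa=True)
    return [InputLocus(locus_id="%s%d" % (id_prefix, i + 1),
                       tree=UTree.from_dendropy(t))
            for i, t in enumerate(trees)]


def collapse_low_support(locus: InputLocus, threshold: float) -> InputLocus:
    """Contract internal edges with support <= threshold (polytomies are
    created; the leaf set is unchanged; unannotated edges are kept)."""
    tree = locus.tree.copy()
    changed = True
    while changed:
        changed = False
        for (u, v) in tree.internal_edges():
            sup = tree.esup.get((min(u, v), max(u, v)))
            if sup is not None and sup <= threshold:
                tree.contract_edge(u, v)
                changed = True
                break
    return InputLocus(locus_id=locus.locus_id, tree=tree)


# ---------------------------------------------------------------------------
# quartet classification helpers


def lca_depth_matrix(tree: UTree, index: Dict[str, int]) -> Dict[Tuple[int, int], int]:
    """depth-of-LCA for every leaf pair, rooting the (unrooted) tree at an
    arbitrary internal node.  Keys are ordered bit-index pairs."""
    internal = [u for u in tree.nodes() if not tree.is_leaf(u)]
    if not internal:
        # two-leaf tree: no quartets possible anyway
        return {}
    root = internal[0]
    depth: Dict[int, int] = {root: 0}
    order: List[Tuple[int, Optional[int]]] = [(root, None)]
    stack = [(root, None)]
    while stack:
        u, parent = stack.pop()
        for v in tree.nbr[u]:
            if v != parent:
                depth[v] = depth[u] + 1
                order.append((v, u))
                stack.append((v, u))
    # leaves under each node, propagated bottom-up
    below: Dict[int, List[int]] = {}
    D: Dict[Tuple[int, int], int] = {}
    for u, parent in reversed(order):
        if tree.is_leaf(u):
            below[u] = [index[tree.labels[u]]]
            continue
        groups = [below[v] for v in tree.nbr[u] if v != parent]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        D[(a, b) if a < b else (b, a)] = depth[u]
        merged = [x for g in groups for x in g]
        below[u] = merged
    return D


def pairing_from_depths(D, i, j, k, l) -> Optional[int]:
    """Resolved pairing of four leaf bit-indices from an LCA-depth map:
    0 = ij|kl, 1 = ik|jl, 2 = il|jk; None if the tree does not resolve
    the quartet.  The pairing whose two within-pair joins are strictly
    deeper than every cross pair is the displayed one."""
    def d(a, b):
        return D[(a, b) if a < b else (b, a)]
    dij, dkl = d(i, j), d(k, l)
    dik, djl = d(i, k), d(j, l)
    dil, djk = d(i, l), d(j, k)
    w = (max(dij, dkl), max(dik, djl), max(dil, djk))
    m = max(w)
    winners = [p for p in range(3) if w[p] == m]
    if len(winners) == 1:
        return winners[0]
    return None


def _min_support_between(tree: UTree, index: Dict[str, int],
                         pair1_mask: int, pair2_mask: int,
                         dm: Dict[Tuple[int, int], int]) -> float:
    """Minimum support over the locus edges separating pair1 from pair2
    (= the edges of the internal path connecting the two cherries)."""
    best = None
    for (u, v) in tree.internal_edges():
        m = dm[(u, v)]
        if (pair1_mask & m == pair1_mask and pair2_mask & m == 0) or \
           (pair2_mask & m == pair2_mask and pair1_mask & m == 0):
            s = tree.esup.get((min(u, v), max(u, v)), DEFAULT_EDGE_WEIGHT)
            best = s if best is None else min(best, s)
    return DEFAULT_EDGE_WEIGHT if best is None else best


# ---------------------------------------------------------------------------
# the scorer


class QuartetScorer:
    """Precomputes locus bitmasks against a fixed taxon order so that many
    candidate species trees can be scored cheaply (the search inner
    loop)."""

    def __init__(self, loci: Sequence[InputLocus], taxa: Sequence[str],
                 weighted: bool = False):
        self.taxa = list(taxa)
        self.index = taxon_index(self.taxa)
        self.weighted = weighted
        self.loci = list(loci)
        # aggregated bipartition loci: (Pmask, Amask) -> total weight
        self._agg: Dict[Tuple[int, int], float] = {}
        self._multi: List[Tuple[InputLocus, Dict, List[Tuple[int, ...]], List[float]]] = []
        for locus in self.loci:
            for lab in locus.leaf_labels:
                if lab not in self.index:
                    raise ValueError(
                        "locus %r leaf %r absent from the species taxon set"
                        % (locus.locus_id, lab))
            if locus.is_bipartition():
                p, a = self._split_masks(locus)
                key = (p, a) if p < a else (a, p)
                w = locus.edge_weight() if weighted else 1.0
                self._agg[key] = self._agg.get(key, 0.0) + w
            elif len(locus.tree.internal_edges()) == 0:
                continue  # star tree: resolves nothing
            else:
                self._multi.append(self._prepare_multi(locus))

    def _split_masks(self, locus: InputLocus) -> Tuple[int, int]:
        side, other = locus.split_sides()
        p = a = 0
        for lab in side:
            p |= 1 << self.index[lab]
        for lab in other:
            a |= 1 << self.index[lab]
        return p, a

    def _prepare_multi(self, locus: InputLocus):
        """Enumerate the quartets the locus resolves, once, as (subset
        bit-indices, pairing, weight) records."""
        lidx = {lab: self.index[lab] for lab in locus.leaf_labels}
        D = lca_depth_matrix(locus.tree, self.index)
        dm = locus.tree.directed_masks(self.index)
        leaves = sorted(lidx.values())
        subsets: List[Tuple[int, int, int, int, int]] = []
        weights: List[float] = []
        for (i, j, k, l) in itertools.combinations(leaves, 4):
            p = pairing_from_depths(D, i, j, k, l)
            if p is None:
                continue
            if self.weighted:
                pairs = [((1 << i) | (1 << j), (1 << k) | (1 << l)),
                         ((1 << i) | (1 << k), (1 << j) | (1 << l)),
                         ((1 << i) | (1 << l), (1 << j) | (1 << k))][p]
                w = _min_support_between(locus.tree, self.index,
                                         pairs[0], pairs[1], dm)
            else:
                w = 1.0
            subsets.append((i, j, k, l, p))
            weights.append(w)
        return (locus, D, subsets, weights)

    # -- scoring ---------------------------------------------------------

    def score(self, species_tree: TreeLike) -> float:
        tree = as_utree(species_tree)
        total = 0.0
        if self._agg:
            pairs = tree.joining_pairs(self.index)
            for (p, a), w in self._agg.items():
                total += w * _split_agreement(pairs, p, a)
        if self._multi:
            D = lca_depth_matrix(tree, self.index)
            for _, _, subsets, weights in self._multi:
                for (i, j, k, l, pl), w in zip(subsets, weights):
                    if pairing_from_depths(D, i, j, k, l) == pl:
                        total += w
        return total if self.weighted else int(round(total))

    def locus_agreements(self, species_tree: TreeLike) -> np.ndarray:
        """Per-locus agreement values, in input order (for PCS etc.)."""
        tree = as_utree(species_tree)
        pairs = tree.joining_pairs(self.index)
        D = None
        out = np.zeros(len(self.loci))
        multi_map = {id(rec[0]): rec for rec in self._multi}
        for n, locus in enumerate(self.loci):
            if locus.is_bipartition():
                p, a = self._split_masks(locus)
                w = locus.edge_weight() if self.weighted else 1.0
                out[n] = w * _split_agreement(pairs, p, a)
            elif id(locus) in multi_map:
                if D is None:
                    D = lca_depth_matrix(tree, self.index)
                _, _, subsets, weights = multi_map[id(locus)]
                out[n] = sum(w for (i, j, k, l, pl), w in zip(subsets, weights)
                             if pairing_from_depths(D, i, j, k, l) == pl)
        return out


def _split_agreement(pairs, P: int, A: int) -> int:
    """Quartets of the species tree matching the split P|A: summed over
    joining-vertex pairs, cherries within P at one end and within A at the
    other (drawn from distinct away-subtrees)."""
    total = 0
    for away_u, away_v in pairs:
        pu = au = pv = av = 0
        if len(away_u) == 2 and len(away_v) == 2:
            m0, m1 = away_u
            pu = (m0 & P).bit_count() * (m1 & P).bit_count()
            au = (m0 & A).bit_count() * (m1 & A).bit_count()
            m0, m1 = away_v
            pv = (m0 & P).bit_count() * (m1 & P).bit_count()
            av = (m0 & A).bit_count() * (m1 & A).bit_count()
        else:  # multifurcating vertex: pairs from distinct subtrees
            pu, au = _cross_pairs(away_u, P, A)
            pv, av = _cross_pairs(away_v, P, A)
        total += pu * av + au * pv
    return total


def _cross_pairs(masks: List[int], P: int, A: int) -> Tuple[int, int]:
    ps = [(m & P).bit_count() for m in masks]
    as_ = [(m & A).bit_count() for m in masks]
    sp, sa = sum(ps), sum(as_)
    p_pairs = (sp * sp - sum(x * x for x in ps)) // 2
    a_pairs = (sa * sa - sum(x * x for x in as_)) // 2
    return p_pairs, a_pairs


# ---------------------------------------------------------------------------
# public operations


def quartet_score(species_tree: TreeLike, loci: Sequence[InputLocus],
                  weighted: bool = False) -> Union[int, float]:
    """Sum over loci and over four-leaf subsets each locus resolves of
    weight x [locus quartet == species-tree quartet].  Unweighted scores
    are integers."""
    tree = as_utree(species_tree)
    if not loci:
        return 0.0 if weighted else 0
    scorer = QuartetScorer(loci, tree.leaf_labels(), weighted=weighted)
    return scorer.score(tree)


@dataclass
class BranchQuartetTally:
    """Induced quartet counts around one internal branch: n1 for the
    species-tree resolution, n2/n3 for the alternatives; EN = number of
    loci contributing at least one quartet here."""

    branch_id: str
    n1: int
    n2: int
    n3: int
    en: int

    @property
    def m(self) -> int:
        return self.n1 + self.n2 + self.n3

    @property
    def frequencies(self) -> Tuple[float, float, float]:
        m = self.m
        if m == 0:
            return (float("nan"),) * 3
        return (self.n1 / m, self.n2 / m, self.n3 / m)


def _branch_clusters(tree: UTree, index, branch_side: Iterable[str]):
    """Locate the internal edge whose split is branch_side|rest and return
    its four adjacent leaf clusters as masks (A,B | C,D)."""
    full = 0
    for lab in tree.leaf_labels():
        full |= 1 << index[lab]
    want = 0
    for lab in branch_side:
        if lab not in index:
            raise ValueError("branch taxon %r not in the species tree" % lab)
        want |= 1 << index[lab]
    if want.bit_count() < 2 or (full & ~want).bit_count() < 2:
        raise ValueError("branch %s is terminal/trivial, no quartet tally"
                         % sorted(branch_side))
    dm = tree.directed_masks(index)
    for (u, v) in tree.internal_edges():
        m = dm[(u, v)]
        if m == want or m == full & ~want:
            if m != want:
                u, v = v, u  # orient: v-side == branch_side
            away_v = [dm[(v, x)] for x in tree.nbr[v] if x != u]
            away_u = [dm[(u, x)] for x in tree.nbr[u] if x != v]
            if len(away_v) != 2 or len(away_u) != 2:
                raise ValueError("branch tally requires a binary species tree")
            A, B = away_v     # the branch_side pair of clusters
            C, D = away_u
            return A, B, C, D
    raise ValueError("no internal branch with side %s" % sorted(branch_side))


def branch_tally(species_tree: TreeLike, loci: Sequence[InputLocus],
                 branch_side: Iterable[str]) -> BranchQuartetTally:
    """Quartet counts (n1, n2, n3) for the three resolutions around the
    internal branch whose one side is ``branch_side``, plus EN.

    For a bipartition locus S|T the count added to n(AB|CD) is
    |A∩S||B∩S||C∩T||D∩T| + |A∩T||B∩T||C∩S||D∩S| and analogously for the
    two alternative pairings; multi-edge loci contribute each four-subset
    (one leaf per cluster) once, classified by the locus's induced
    quartet."""
    tree = as_utree(species_tree)
    index = taxon_index(tree.leaf_labels())
    A, B, C, D = _branch_clusters(tree, index, branch_side)
    n = [0, 0, 0]
    en = 0
    for locus in loci:
        contrib = _tally_one(locus, index, A, B, C, D)
        if sum(contrib) > 0:
            en += 1
        for i in range(3):
            n[i] += contrib[i]
    side = sorted(branch_side)
    return BranchQuartetTally(branch_id=",".join(side),
                              n1=n[0], n2=n[1], n3=n[2], en=en)


def _tally_one(locus: InputLocus, index, A, B, C, D) -> Tuple[int, int, int]:
    if locus.is_bipartition():
        side, other = locus.split_sides()
        S = T = 0
        for lab in side:
            S |= 1 << index[lab]
        for lab in other:
            T |= 1 << index[lab]

        def cnt(X, Y):
            return (X & Y).bit_count()

        n1 = cnt(A, S) * cnt(B, S) * cnt(C, T) * cnt(D, T) \
            + cnt(A, T) * cnt(B, T) * cnt(C, S) * cnt(D, S)
        n2 = cnt(A, S) * cnt(C, S) * cnt(B, T) * cnt(D, T) \
            + cnt(A, T) * cnt(C, T) * cnt(B, S) * cnt(D, S)
        n3 = cnt(A, S) * cnt(D, S) * cnt(B, T) * cnt(C, T) \
            + cnt(A, T) * cnt(D, T) * cnt(B, S) * cnt(C, S)
        return n1, n2, n3
    if len(locus.tree.internal_edges()) == 0:
        return 0, 0, 0
    Dm = lca_depth_matrix(locus.tree, index)
    leafmask = 0
    for lab in locus.leaf_labels:
        leafmask |= 1 << index[lab]

    def members(X):
        out = []
        m = X & leafmask
        while m:
            low = m & -m
            out.append(low.bit_length() - 1)
            m ^= low
        return out

    la, lb, lc, ld = members(A), members(B), members(C), members(D)
    n = [0, 0, 0]
    for a in la:
        for b in lb:
            for c in lc:
                for d in ld:
                    # argument order (a,b,c,d) makes pairing 0 = AB|CD,
                    # 1 = AC|BD, 2 = AD|BC directly
                    p = pairing_from_depths(Dm, a, b, c, d)
                    if p is not None:
                        n[p] += 1
    return tuple(n)


def all_branch_tallies(species_tree: TreeLike, loci: Sequence[InputLocus]
                       ) -> List[BranchQuartetTally]:
    tree = as_utree(species_tree)
    index = taxon_index(tree.leaf_labels())
    out = []
    for (u, v), mask in tree.split_masks(index).items():
        out.append(branch_tally(tree, loci, canonical_side(mask, index)))
    return out


def canonical_side(mask: int, index: Dict[str, int]) -> List[str]:
    """The smaller side of a split (ties broken lexicographically), used
    to name branches consistently."""
    inv = {i: lab for lab, i in index.items()}
    side = sorted(inv[i] for i in inv if mask >> i & 1)
    other = sorted(set(inv.values()) - set(side))
    if (len(other), other) < (len(side), side):
        return other
    return side


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_score(species_tree: TreeLike, loci: Sequence[InputLocus],
                      weighted: bool = False, max_leaves: int = 12
                      ) -> Union[int, float]:
    """Independent oracle: explicit enumeration of every four-subset of
    every locus, with pairings resolved by direct split inspection.
    Guarded to small trees."""
    tree = as_utree(species_tree)
    labels = tree.leaf_labels()
    if len(labels) > max_leaves:
        raise ValueError("brute_force_score is limited to %d leaves"
                         % max_leaves)
    index = taxon_index(labels)
    total = 0.0
    for locus in loci:
        lv = sorted(locus.leaf_labels)
        dm = None
        for quad in itertools.combinations(lv, 4):
            pl = quartet_pairing(locus.tree, index, quad)
            if pl is None:
                continue
            ps = quartet_pairing(tree, index, quad)
            if ps != pl:
                continue
            if weighted:
                if len(locus.tree.internal_edges()) == 1:
                    total += locus.edge_weight()
                else:
                    if dm is None:
                        dm = locus.tree.directed_masks(index)
                    pairs = [((quad[0], quad[1]), (quad[2], quad[3])),
                             ((quad[0], quad[2]), (quad[1], quad[3])),
                             ((quad[0], quad[3]), (quad[1], quad[2]))][pl]
                    m1 = (1 << index[pairs[0][0]]) | (1 << index[pairs[0][1]])
                    m2 = (1 << index[pairs[1][0]]) | (1 << index[pairs[1][1]])
                    total += _min_support_between(locus.tree, index, m1, m2, dm)
            else:
                total += 1
    return total if weighted else int(total)
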