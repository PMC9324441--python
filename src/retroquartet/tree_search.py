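"""Species-tree search under the quartet-agreement objective.

Exhaustive enumeration for small taxon sets (the exact oracle), seeded
random-restart NNI hill-climbing for larger ones, anti-constraint
searches (the best tree *lacking* a focal clade), and the SDPquartets
pathway (per-quartet parsimony assembled by matrix representation with
parsimony).  All searches are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._unrooted import UTree, enumerate_topologies, taxon_index
from .quartet_engine import (InputLocus, QuartetScorer, TreeLike, as_utree,
                             locus_from_bipartition)
from .rimatrix import RIMatrix, to_bipartitions

EXHAUSTIVE_MAX_TAXA = 9     # 135,135 unrooted binary topologies at 9


@dataclass
class SearchResult:
    """A species tree with its quartet score and how it was found."""

    tree: UTree
    score: float
    mode: str
    restarts: int = 1
    seed: Optional[int] = None
    tie: bool = False
    co_optimal: List[str] = field(default_factory=list)
    extras: Dict = field(default_factory=dict)

    @property
    def newick(self) -> str:
        return self.tree.canonical_newick()


def _clade_mask(clade: Iterable[str], index: Dict[str, int]) -> int:
    mask = 0
    for lab in clade:
        if lab not in index:
            raise ValueError("clade taxon %r not in the taxon set" % lab)
        mask |= 1 << index[lab]
    return mask


def tree_has_clade(tree: TreeLike, clade: Iterable[str]) -> bool:
    """Does the (unrooted) tree contain the split clade|rest?"""
    t = as_utree(tree)
    index = taxon_index(t.leaf_labels())
    return t.has_split(_clade_mask(clade, index), index)


def _displays_backbone(tree: UTree, backbone: UTree,
                       index: Dict[str, int]) -> bool:
    bb_leaves = backbone.leaf_labels()
    bmask = _clade_mask(bb_leaves, index)
    tree_sides = set()
    for m in tree.split_masks(index).values():
        tree_sides.add(m & bmask)
        tree_sides.add(bmask & ~m)
    for m in backbone.split_masks(index).values():
        side = m & bmask
        other = bmask & ~side
        if side.bit_count() < 2 or other.bit_count() < 2:
            continue
        if side not in tree_sides and other not in tree_sides:
            return False
    return True


def _allowed(tree: UTree, index, forbidden_mask: Optional[int],
             backbone: Optional[UTree]) -> bool:
    if forbidden_mask is not None and tree.has_split(forbidden_mask, index):
        return False
    if backbone is not None and not _displays_backbone(tree, backbone, index):
        return False
    return True


def exhaustive_search(loci: Sequence[InputLocus], taxa: Sequence[str],
                      weighted: bool = False,
                      forbidden_clade: Optional[Iterable[str]] = None,
                      backbone: Optional[TreeLike] = None) -> SearchResult:
    """Score every unrooted binary topology (<= 9 taxa); ties are broken
    by the lexicographically least canonical newick and flagged."""
    taxa = sorted(taxa)
    if len(taxa) > EXHAUSTIVE_MAX_TAXA:
        raise ValueError("exhaustive search capped at %d taxa"
                         % EXHAUSTIVE_MAX_TAXA)
    if len(taxa) < 4:
        raise ValueError("need >= 4 taxa")
    index = taxon_index(taxa)
    fmask = (_clade_mask(forbidden_clade, index)
             if forbidden_clade is not None else None)
    if fmask is not None:
        _check_forbidden(fmask, len(taxa))
    bb = as_utree(backbone) if backbone is not None else None
    scorer = QuartetScorer(loci, taxa, weighted=weighted)
    best: Optional[float] = None
    winners: List[str] = []
    for tree in enumerate_topologies(taxa):
        if not _allowed(tree, index, fmask, bb):
            continue
        s = scorer.score(tree)
        if best is None or s > best:
            best = s
            winners = [tree.canonical_newick()]
        elif s == best:
            winners.append(tree.canonical_newick())
    if best is None:
        raise ValueError("no admissible topology (constraints too strict)")
    winners.sort()
    return SearchResult(tree=UTree.from_newick(winners[0]), score=best,
                        mode="exhaustive", tie=len(winners) > 1,
                        co_optimal=winners)


def _check_forbidden(fmask: int, n: int) -> None:
    k = fmask.bit_count()
    if k < 2 or k > n - 2:
        raise ValueError("forbidden clade must have size in [2, n-2]")


def _random_admissible(taxa, rng, index, fmask, bb, max_tries=500) -> UTree:
    for _ in range(max_tries):
        t = UTree.random_topology(taxa, rng)
        if _allowed(t, index, fmask, bb):
            return t
    raise ValueError("could not sample a start tree satisfying constraints")


def hillclimb_search(loci: Sequence[InputLocus], taxa: Sequence[str],
                     restarts: int = 20, seed: Optional[int] = None,
                     candidate_pool: Optional[Sequence[TreeLike]] = None,
                     weighted: bool = False,
                     forbidden_clade: Optional[Iterable[str]] = None,
                     backbone: Optional[TreeLike] = None) -> SearchResult:
    """Seeded random-restart steepest-ascent NNI.  Candidate-pool trees
    (if given) are used as the first starting points, broadening the
    search the way extra input trees broaden an ASTRAL search space."""
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    taxa = sorted(taxa)
    index = taxon_index(taxa)
    fmask = (_clade_mask(forbidden_clade, index)
             if forbidden_clade is not None else None)
    if fmask is not None:
        _check_forbidden(fmask, len(taxa))
    bb = as_utree(backbone) if backbone is not None else None
    rng = np.random.default_rng(seed)
    scorer = QuartetScorer(loci, taxa, weighted=weighted)

    starts: List[UTree] = []
    if candidate_pool:
        for t in candidate_pool:
            cand = as_utree(t)
            if sorted(cand.leaf_labels()) == taxa and \
                    _allowed(cand, index, fmask, bb):
                starts.append(cand)
    while len(starts) < restarts:
        starts.append(_random_admissible(taxa, rng, index, fmask, bb))

    best_tree: Optional[UTree] = None
    best_score: Optional[float] = None
    seen_best: set = set()
    for start in starts:
        tree, score = _climb(start, scorer, index, fmask, bb)
        key = tree.canonical_newick()
        if best_score is None or score > best_score:
            best_score, best_tree = score, tree
            seen_best = {key}
        elif score == best_score:
            seen_best.add(key)
    winners = sorted(seen_best)
    if winners[0] != best_tree.canonical_newick():
        best_tree = UTree.from_newick(winners[0])
    return SearchResult(tree=best_tree, score=best_score, mode="hillclimb",
                        restarts=len(starts), seed=seed,
                        tie=len(winners) > 1, co_optimal=winners)


def _climb(tree: UTree, scorer: QuartetScorer, index,
           fmask, bb) -> Tuple[UTree, float]:
    score = scorer.score(tree)
    improved = True
    while improved:
        improved = False
        best_nb, best_s = None, score
        for nb in tree.nni_neighbors():
            if not _allowed(nb, index, fmask, bb):
                continue
            s = scorer.score(nb)
            if s > best_s:
                best_s, best_nb = s, nb
        if best_nb is not None:
            tree, score = best_nb, best_s
            improved = True
    return tree, score


def anticonstraint_search(loci: Sequence[InputLocus], taxa: Sequence[str],
                          forbidden_clade: Iterable[str],
                          restarts: int = 20, seed: Optional[int] = None,
                          candidate_pool: Optional[Sequence[TreeLike]] = None,
                          weighted: bool = False,
                          exhaustive: Optional[bool] = None) -> SearchResult:
    """Best tree whose splits do not include forbidden_clade|rest."""
    taxa = sorted(taxa)
    if exhaustive is None:
        exhaustive = len(taxa) <= EXHAUSTIVE_MAX_TAXA
    if exhaustive:
        res = exhaustive_search(loci, taxa, weighted=weighted,
                                forbidden_clade=forbidden_clade)
    else:
        res = hillclimb_search(loci, taxa, restarts=restarts, seed=seed,
                               candidate_pool=candidate_pool,
                               weighted=weighted,
                               forbidden_clade=forbidden_clade)
    res.mode = "anticonstraint+" + res.mode
    return res


# ---------------------------------------------------------------------------
# SDPquartets: per-quartet parsimony + MRP supertree


@dataclass
class MRPRow:
    """One candidate quartet tree as a binary character: the paired taxa
    coded 1, the other pair 0, all remaining taxa missing."""

    subset: Tuple[str, str, str, str]
    pair: Tuple[str, str]            # the taxa coded 1
    count: int                       # characters supporting this pairing

    @property
    def other_pair(self) -> Tuple[str, str]:
        return tuple(sorted(set(self.subset) - set(self.pair)))


@dataclass
class MRPMatrix:
    rows: List[MRPRow]

    def __len__(self) -> int:
        return len(self.rows)

    def as_loci(self) -> List[InputLocus]:
        out = []
        for i, row in enumerate(self.rows):
            out.append(InputLocus(
                locus_id="mrp%d" % (i + 1),
                tree=UTree.from_split(sorted(row.pair),
                                      sorted(row.other_pair))))
        return out


def build_mrp_matrix(m: RIMatrix) -> MRPMatrix:
    """Unordered parsimony on every four-taxon subset: among the three
    quartet topologies, those of minimum length over the characters
    informative for the subset (complete 2v2 patterns; all other
    characters add equal length to every topology and are skipped) are
    encoded as MRP rows.  Ties contribute one row each."""
    from itertools import combinations
    labels = list(m.taxa.labels)
    if len(labels) < 4:
        raise ValueError("need >= 4 taxa for SDPquartets")
    S = m.states
    rows: List[MRPRow] = []
    idx = {lab: i for i, lab in enumerate(labels)}
    for quad in combinations(sorted(labels), 4):
        ii = [idx[q] for q in quad]
        sub = S[ii, :]
        complete = (sub != -1).all(axis=0)
        sub = sub[:, complete]
        informative = sub.sum(axis=0) == 2
        sub = sub[:, informative]
        if sub.shape[1] == 0:
            continue
        # pairing of the two present-coded taxa
        c = np.zeros(3, dtype=int)
        pres01 = (sub[0] == 1) & (sub[1] == 1)
        pres02 = (sub[0] == 1) & (sub[2] == 1)
        pres03 = (sub[0] == 1) & (sub[3] == 1)
        c[0] = int(pres01.sum() + ((sub[2] == 1) & (sub[3] == 1)).sum())
        c[1] = int(pres02.sum() + ((sub[1] == 1) & (sub[3] == 1)).sum())
        c[2] = int(pres03.sum() + ((sub[1] == 1) & (sub[2] == 1)).sum())
        best = c.max()
        pairs = [(quad[0], quad[1]), (quad[0], quad[2]), (quad[0], quad[3])]
        for t in range(3):
            if c[t] == best:
                rows.append(MRPRow(subset=quad, pair=pairs[t],
                                   count=int(c[t])))
    return MRPMatrix(rows=rows)


def mrp_treelength(mrp: MRPMatrix, tree: TreeLike) -> int:
    """Binary Fitch length of the MRP matrix on the tree: a quartet row
    costs 1 step when the tree displays its quartet, else 2, so the
    treelength is #rows + #violated rows."""
    t = as_utree(tree)
    scorer = QuartetScorer(mrp.as_loci(), t.leaf_labels())
    displayed = int(scorer.score(t))
    return 2 * len(mrp) - displayed


def sdp_quartets(m: RIMatrix, backbone_constraint: Optional[TreeLike] = None,
                 restarts: int = 20, seed: Optional[int] = None,
                 exhaustive: Optional[bool] = None) -> SearchResult:
    """SDPquartets: quartet parsimony on every 4-subset, assembled into a
    species tree by a parsimony search over the MRP matrix (the MRP
    objective is equivalent to maximising the number of displayed quartet
    rows, so the hill-climb machinery is reused)."""
    taxa = sorted(m.taxa.labels)
    mrp = build_mrp_matrix(m)
    loci = mrp.as_loci()
    if exhaustive is None:
        exhaustive = len(taxa) <= EXHAUSTIVE_MAX_TAXA and not backbone_constraint
    if exhaustive:
        res = exhaustive_search(loci, taxa, backbone=backbone_constraint)
    else:
        res = hillclimb_search(loci, taxa, restarts=restarts, seed=seed,
                               backbone=backbone_constraint)
    length = 2 * len(mrp) - int(res.score)
    res.mode = "sdpquartets+" + res.mode
    res.extras.update({"mrp_rows": len(mrp), "mrp_treelength": length,
                       "mrp": mrp})
    return res


def infer_species_tree(m: RIMatrix, method: str = "quartet",
                       min_side: int = 2, **kwargs) -> SearchResult:
    """Convenience wrapper: matrix -> bipartitions -> search."""
    if method == "sdpq":
        return sdp_quartets(m, **kwargs)
    bps = to_bipartitions(m, min_side=min_side)
    loci = [locus_from_bipartition(bp) for bp in bps]
    taxa = sorted(m.taxa.labels)
    if kwargs.pop("exhaustive", len(taxa) <= EXHAUSTIVE_MAX_TAXA):
        return exhaustive_search(loci, taxa, **kwargs)
    return hillclimb_search(loci, taxa, **kwargs)
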