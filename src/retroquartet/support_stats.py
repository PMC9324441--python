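"""Clade support and stability for quartet-based RI species trees.

Four complementary measures:

* partitioned coalescence support (PCS): the quartet-score difference
  between the optimal tree and the best tree lacking a focal clade
  ("coalescence support"), partitioned exactly among the input loci;
* the locus-removal index: a greedy estimate (an upper bound) of the
  minimum number of loci whose removal collapses a clade, removing the
  top-PCS locus and re-searching at every step;
* character bootstrap percentages over resampled pseudoreplicates;
* linked-support reports: which other clades an anti-constraint tree or
  a joint locus removal takes down along with the focal clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._unrooted import UTree, taxon_index
from .quartet_engine import InputLocus, QuartetScorer, TreeLike, as_utree
from .tree_search import (SearchResult, anticonstraint_search,
                          exhaustive_search, hillclimb_search,
                          tree_has_clade, EXHAUSTIVE_MAX_TAXA)


def _search(loci, taxa, exhaustive=None, restarts=20, seed=None,
            candidate_pool=None, weighted=False) -> SearchResult:
    taxa = sorted(taxa)
    if exhaustive is None:
        exhaustive = len(taxa) <= EXHAUSTIVE_MAX_TAXA
    if exhaustive:
        return exhaustive_search(loci, taxa, weighted=weighted)
    return hillclimb_search(loci, taxa, restarts=restarts, seed=seed,
                            candidate_pool=candidate_pool, weighted=weighted)


def _tree_splits(tree: UTree) -> List[FrozenSet[str]]:
    """Non-trivial splits as frozensets of the side not holding the
    alphabetically first taxon."""
    index = taxon_index(tree.leaf_labels())
    inv = {i: lab for lab, i in index.items()}
    return [frozenset(inv[i] for i in range(len(inv)) if m >> i & 1)
            for m in tree.split_masks(index).values()]


# ---------------------------------------------------------------------------
# PCS


@dataclass
class PCSTable:
    clade: FrozenSet[str]
    table: pd.DataFrame                  # locus_id, pcs (sorted descending)
    coalescence_support: float
    optimal_score: float
    anti_score: float
    anti_tree: UTree

    def top_loci(self, k: int) -> List:
        return list(self.table["locus_id"].iloc[:k])


def pcs(loci: Sequence[InputLocus], optimal: Union[SearchResult, TreeLike],
        clade: Iterable[str], weighted: bool = False,
        anti: Optional[Union[SearchResult, TreeLike]] = None,
        **search_kwargs) -> PCSTable:
    """Partitioned coalescence support of a clade: per-locus share of the
    score difference between the optimal tree and the best tree lacking
    the clade.  The per-locus values sum exactly to the coalescence
    support."""
    opt_tree = optimal.tree if isinstance(optimal, SearchResult) \
        else as_utree(optimal)
    clade = frozenset(clade)
    if not tree_has_clade(opt_tree, clade):
        raise ValueError("clade %s absent from the optimal tree"
                         % sorted(clade))
    taxa = sorted(opt_tree.leaf_labels())
    if anti is None:
        anti_res = anticonstraint_search(loci, taxa, clade, weighted=weighted,
                                         **search_kwargs)
        anti_tree = anti_res.tree
    else:
        anti_tree = anti.tree if isinstance(anti, SearchResult) \
            else as_utree(anti)
    scorer = QuartetScorer(loci, taxa, weighted=weighted)
    a_opt = scorer.locus_agreements(opt_tree)
    a_anti = scorer.locus_agreements(anti_tree)
    vals = a_opt - a_anti
    table = pd.DataFrame({"locus_id": [l.locus_id for l in loci],
                          "pcs": vals})
    table = table.sort_values(["pcs", "locus_id"],
                              ascending=[False, True],
                              key=lambda s: s if s.name == "pcs"
                              else s.astype(str)).reset_index(drop=True)
    return PCSTable(clade=clade, table=table,
                    coalescence_support=float(vals.sum()),
                    optimal_score=float(a_opt.sum()),
                    anti_score=float(a_anti.sum()),
                    anti_tree=anti_tree)


# ---------------------------------------------------------------------------
# locus-removal index


@dataclass
class RemovalIndexResult:
    clade: FrozenSet[str]
    index: Optional[int]                 # None when flagged unbounded
    removed_locus_ids: List
    unbounded: bool
    steps: List[Dict] = field(default_factory=list)

    @property
    def is_upper_bound(self) -> bool:
        """The greedy ranked-removal procedure bounds the true minimum
        from above."""
        return True


def removal_index(loci: Sequence[InputLocus], clade: Iterable[str],
                  max_removals: Optional[int] = None,
                  weighted: bool = False, **search_kwargs
                  ) -> RemovalIndexResult:
    """Greedy locus-removal index: repeatedly remove the top-PCS locus
    and re-search (both the optimum and the anti-constraint tree are
    recomputed after every removal) until the focal clade drops out of
    the optimal tree."""
    clade = frozenset(clade)
    current = list(loci)
    taxa = sorted({lab for l in loci for lab in l.leaf_labels})
    res = _search(current, taxa, weighted=weighted, **search_kwargs)
    if not tree_has_clade(res.tree, clade):
        raise ValueError("clade %s absent from the current optimum"
                         % sorted(clade))
    removed: List = []
    steps: List[Dict] = []
    cap = max_removals if max_removals is not None else len(loci)
    while len(removed) < cap:
        table = pcs(current, res, clade, weighted=weighted, **search_kwargs)
        if table.table["pcs"].iloc[0] <= 0:
            return RemovalIndexResult(clade=clade, index=None,
                                      removed_locus_ids=removed,
                                      unbounded=True, steps=steps)
        drop_id = table.table["locus_id"].iloc[0]  # column access keeps dtype
        current = [l for l in current if l.locus_id != drop_id]
        removed.append(drop_id)
        res = _search(current, taxa, weighted=weighted, **search_kwargs)
        collapsed = not tree_has_clade(res.tree, clade)
        steps.append({"removed": drop_id, "score": res.score,
                      "clade_present": not collapsed,
                      "tree": res.newick})
        if collapsed:
            return RemovalIndexResult(clade=clade, index=len(removed),
                                      removed_locus_ids=removed,
                                      unbounded=False, steps=steps)
    return RemovalIndexResult(clade=clade, index=None,
                              removed_locus_ids=removed,
                              unbounded=True, steps=steps)


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    percentages: Dict[FrozenSet[str], float]
    n_replicates: int
    seed: Optional[int]
    reference: UTree

    def percent(self, clade: Iterable[str]) -> float:
        key = frozenset(clade)
        taxa = set(self.reference.leaf_labels())
        if key not in self.percentages:
            comp = frozenset(taxa - key)
            if comp in self.percentages:
                key = comp
            else:
                raise KeyError("clade %s not in the reference tree"
                               % sorted(clade))
        return self.percentages[key]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"clade": ",".join(sorted(c)), "bootstrap_pct": p}
                for c, p in sorted(self.percentages.items(),
                                   key=lambda kv: sorted(kv[0]))]
        return pd.DataFrame(rows)


def bootstrap(loci: Sequence[InputLocus], n_replicates: int = 100,
              seed: Optional[int] = None,
              reference: Optional[Union[SearchResult, TreeLike]] = None,
              candidate_pool: Optional[Sequence[TreeLike]] = None,
              weighted: bool = False, **search_kwargs) -> BootstrapResult:
    """Character bootstrap: resample loci with replacement, re-search per
    pseudoreplicate (replicate seeds derived from the master seed), map
    clade frequencies onto the reference optimal tree."""
    if n_replicates < 1:
        raise ValueError("need >= 1 pseudoreplicate")
    taxa = sorted({lab for l in loci for lab in l.leaf_labels})
    if reference is None:
        ref_res = _search(loci, taxa, weighted=weighted, seed=seed,
                          candidate_pool=candidate_pool, **search_kwargs)
        ref_tree = ref_res.tree
    else:
        ref_tree = reference.tree if isinstance(reference, SearchResult) \
            else as_utree(reference)
    ref_splits = _tree_splits(ref_tree)
    hits = {c: 0 for c in ref_splits}
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    pool = [ref_tree] + ([as_utree(t) for t in candidate_pool]
                         if candidate_pool else [])
    for r in range(n_replicates):
        idx = np.random.default_rng(int(rep_seeds[r])).integers(
            0, len(loci), size=len(loci))
        sample = [loci[i] for i in idx]
        res = _search(sample, taxa, weighted=weighted,
                      seed=int(rep_seeds[r]), candidate_pool=pool,
                      **search_kwargs)
        for c in ref_splits:
            if tree_has_clade(res.tree, c):
                hits[c] += 1
    pct = {c: 100.0 * h / n_replicates for c, h in hits.items()}
    return BootstrapResult(percentages=pct, n_replicates=n_replicates,
                           seed=seed, reference=ref_tree)


# ---------------------------------------------------------------------------
# linked support


@dataclass
class LinkedSupportReport:
    anti_losses: Dict[FrozenSet[str], List[FrozenSet[str]]]
    removal_losses: List[Tuple[List, List[FrozenSet[str]]]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for clade, lost in sorted(self.anti_losses.items(),
                                  key=lambda kv: sorted(kv[0])):
            rows.append({
                "clade": ",".join(sorted(clade)),
                "also_lost": " | ".join(",".join(sorted(c)) for c in lost),
                "n_linked": len(lost)})
        return pd.DataFrame(rows)


def linked_support_report(loci: Sequence[InputLocus],
                          optimal: Union[SearchResult, TreeLike],
                          clades: Sequence[Iterable[str]],
                          removal_sets: Optional[Sequence[Sequence]] = None,
                          weighted: bool = False,
                          **search_kwargs) -> LinkedSupportReport:
    """For each focal clade, the *other* optimal-tree clades that its
    anti-constraint tree also lacks; optionally, for each locus-removal
    set, the clades that collapse together after removal."""
    opt_tree = optimal.tree if isinstance(optimal, SearchResult) \
        else as_utree(optimal)
    taxa = sorted(opt_tree.leaf_labels())
    opt_splits = _tree_splits(opt_tree)
    anti_losses: Dict[FrozenSet[str], List[FrozenSet[str]]] = {}
    for clade in clades:
        clade = frozenset(clade)
        if not tree_has_clade(opt_tree, clade):
            raise ValueError("clade %s absent from the optimal tree"
                             % sorted(clade))
        anti = anticonstraint_search(loci, taxa, clade, weighted=weighted,
                                     **search_kwargs)
        lost = [c for c in opt_splits
                if not tree_has_clade(anti.tree, c)
                and c != clade and frozenset(set(taxa) - c) != clade]
        anti_losses[clade] = lost
    removal_losses = []
    if removal_sets:
        for rem in removal_sets:
            rem_set = set(rem)
            remaining = [l for l in loci if l.locus_id not in rem_set]
            res = _search(remaining, taxa, weighted=weighted, **search_kwargs)
            collapsed = [c for c in opt_splits
                         if not tree_has_clade(res.tree, c)]
            removal_losses.append((list(rem), collapsed))
    return LinkedSupportReport(anti_losses=anti_losses,
                               removal_losses=removal_losses)
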