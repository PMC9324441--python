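"""Unordered parsimony of binary RI characters on fixed species trees.

A character that can be explained by a single state change on exactly one
branch is a "perfectly congruent synapomorphy" of the clade below that
branch (when the derived state is presence: one insertion, no homoplasy,
no hemiplasy).  Clades of a species tree supported by no such character
are "emergent" - held up purely by conflicting characters.  Characters
that are cleanly synapomorphic on one tree (say, a combined-evidence
tree) but not on another (the RI-only tree) are "hidden synapomorphies".

Missing entries are treated as the full state set {0,1}; parsimony
lengths are computed by exact dynamic programming over root-state
assignments, valid for multifurcating trees too.  Polarity (insertion vs
loss) follows the rooting of the input tree: the derived state sits on
the root-distal side of the change edge, and when both polarizations are
equally parsimonious (a change across the root edge) the insertion
reading is preferred, since precise excision of a retroelement is rare.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import dendropy

from .rimatrix import RIMatrix, MISSING, PRESENT, ABSENT

TreeInput = Union[str, "dendropy.Tree"]

INF = math.inf


class _RNode:
    __slots__ = ("children", "label", "clade")

    def __init__(self):
        self.children: List["_RNode"] = []
        self.label: Optional[str] = None
        self.clade: FrozenSet[str] = frozenset()


def _as_rooted(tree: TreeInput) -> _RNode:
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick",
                                 suppress_internal_node_taxa=True)

    def conv(nd) -> _RNode:
        r = _RNode()
        if nd.is_leaf():
            r.label = nd.taxon.label if nd.taxon is not None else nd.label
            r.clade = frozenset([r.label])
        else:
            r.children = [conv(c) for c in nd.child_nodes()]
            r.clade = frozenset().union(*(c.clade for c in r.children))
        return r

    return conv(tree.seed_node)


@dataclass
class FitchResult:
    """Parsimony length of one character plus, for single-step
    characters, the set of branches that can host the change."""

    locus_id: Union[int, str]
    length: int
    change_edges: List[Tuple[FrozenSet[str], int]] = field(default_factory=list)
    # (clade on the derived side, derived state), one entry per unrooted edge

    @property
    def unequivocal(self) -> bool:
        return self.length == 1 and len(self.change_edges) == 1


def _char_map(character, taxa: Optional[Sequence[str]] = None
              ) -> Dict[str, int]:
    """Normalize a character to {label: 0/1}; missing entries dropped."""
    if isinstance(character, Mapping):
        items = character.items()
    else:
        if taxa is None:
            raise ValueError("taxa required when character is a sequence")
        items = zip(taxa, character)
    out = {}
    for lab, s in items:
        if s in ("?", MISSING, None):
            continue
        s = int(s)
        if s not in (0, 1):
            raise ValueError("invalid state %r for taxon %s" % (s, lab))
        out[lab] = s
    return out


def fitch_length(character, tree: TreeInput,
                 taxa: Optional[Sequence[str]] = None,
                 locus_id: Union[int, str] = 0) -> FitchResult:
    """Minimum number of state changes of a binary character on a tree,
    with missing entries free to take either state.

    For length-1 characters the feasible change edges are exactly the
    tree edges whose split separates the observed 1s from the observed
    0s (terminal edges included); exactly one such edge makes the
    character unequivocal."""
    root = _as_rooted(tree)
    obs = _char_map(character, taxa)
    if not obs:
        raise ValueError("character %r has no scored taxon" % (locus_id,))
    missing_from_tree = set(obs) - root.clade
    if missing_from_tree:
        raise ValueError("tree lacks scored taxa: %s"
                         % sorted(missing_from_tree))

    def cost(node: _RNode) -> Tuple[float, float]:
        if node.label is not None:
            s = obs.get(node.label)
            if s is None:
                return (0.0, 0.0)
            return (0.0, INF) if s == 0 else (INF, 0.0)
        c0 = c1 = 0.0
        for ch in node.children:
            k0, k1 = cost(ch)
            c0 += min(k0, k1 + 1.0)
            c1 += min(k1, k0 + 1.0)
        return c0, c1

    c0, c1 = cost(root)
    length = int(min(c0, c1))

    edges: List[Tuple[FrozenSet[str], int]] = []
    if length == 1:
        ones = frozenset(l for l, s in obs.items() if s == 1)
        zeros = frozenset(l for l, s in obs.items() if s == 0)
        full = root.clade
        by_split: Dict[FrozenSet[FrozenSet[str]], Tuple[FrozenSet[str], int]] = {}

        def walk(node: _RNode):
            for ch in node.children:
                below = ch.clade
                split = frozenset([below, full - below])
                if ones <= below and not (zeros & below):
                    by_split[split] = (below, 1)   # insertion wins ties
                elif zeros <= below and not (ones & below):
                    by_split.setdefault(split, (below, 0))
                walk(ch)

        walk(root)
        edges = sorted(by_split.values(), key=lambda e: sorted(e[0]))
    return FitchResult(locus_id=locus_id, length=length, change_edges=edges)


@dataclass
class SynapomorphyReport:
    """Per-clade counts of perfectly congruent RI synapomorphies."""

    counts: Dict[FrozenSet[str], List] = field(default_factory=dict)
    losses: Dict[FrozenSet[str], List] = field(default_factory=dict)
    equivocal: List = field(default_factory=list)

    def count(self, clade: Sequence[str]) -> int:
        return len(self.counts.get(frozenset(clade), []))

    def emergent(self, clade: Sequence[str]) -> bool:
        key = frozenset(clade)
        if key not in self.counts:
            raise KeyError("clade %s not in the species tree" % sorted(clade))
        return len(self.counts[key]) == 0

    @property
    def emergent_clades(self) -> List[FrozenSet[str]]:
        return [c for c, ids in self.counts.items() if not ids]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for clade, ids in sorted(self.counts.items(), key=lambda kv: sorted(kv[0])):
            rows.append({
                "clade": ",".join(sorted(clade)),
                "n_synapomorphies": len(ids),
                "loci": ";".join(str(i) for i in ids),
                "n_losses": len(self.losses.get(clade, [])),
                "emergent": len(ids) == 0,
            })
        return pd.DataFrame(rows)


def _internal_clades(tree: TreeInput) -> List[FrozenSet[str]]:
    root = _as_rooted(tree)
    out = []

    def walk(node):
        for ch in node.children:
            if ch.children and len(ch.clade) < len(root.clade):
                out.append(ch.clade)
            walk(ch)

    walk(root)
    return out


def synapomorphy_scan(m: RIMatrix, tree: TreeInput,
                      relaxed_ambiguity: bool = False) -> SynapomorphyReport:
    """Count, for every internal clade of the tree, the characters whose
    single unequivocal change is an insertion on the clade's subtending
    branch.  Clades with zero such characters are emergent.

    With ``relaxed_ambiguity`` a length-1 character whose change edge is
    ambiguous (because of missing data) is assigned to the shallowest
    feasible insertion edge instead of being set aside as equivocal."""
    clades = _internal_clades(tree)
    report = SynapomorphyReport(
        counts={c: [] for c in clades},
        losses={c: [] for c in clades})
    taxa = list(m.taxa.labels)
    for j, locus_id in enumerate(m.locus_ids):
        col = m.states[:, j]
        if (col != MISSING).sum() == 0:
            continue
        res = fitch_length(col, tree, taxa=taxa, locus_id=locus_id)
        if res.length != 1:
            continue
        gains = [(cl, d) for (cl, d) in res.change_edges if d == 1]
        if res.unequivocal:
            clade, derived = res.change_edges[0]
            if derived == 1:
                if clade in report.counts:
                    report.counts[clade].append(locus_id)
            else:
                if clade in report.losses:
                    report.losses[clade].append(locus_id)
        elif relaxed_ambiguity and gains:
            shallowest = min((len(cl) for cl, _ in gains))
            cands = [cl for cl, _ in gains if len(cl) == shallowest]
            if len(cands) == 1 and cands[0] in report.counts:
                report.counts[cands[0]].append(locus_id)
            else:
                report.equivocal.append(locus_id)
        else:
            report.equivocal.append(locus_id)
    return report


@dataclass
class HiddenSynapomorphyReport:
    """Characters cleanly synapomorphic on tree_b but not on tree_a,
    grouped by the tree_b clade they support."""

    per_clade: Dict[FrozenSet[str], List] = field(default_factory=dict)

    @property
    def n_characters(self) -> int:
        return sum(len(v) for v in self.per_clade.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"clade": ",".join(sorted(c)),
                 "loci": ";".join(str(i) for i in ids),
                 "n_hidden": len(ids)}
                for c, ids in sorted(self.per_clade.items(),
                                     key=lambda kv: sorted(kv[0]))]
        return pd.DataFrame(rows)


def hidden_synapomorphies(m: RIMatrix, tree_a: TreeInput, tree_b: TreeInput
                          ) -> HiddenSynapomorphyReport:
    """Characters that are unequivocal insertion synapomorphies for an
    internal clade of tree_b but not for any internal clade of tree_a
    (e.g. support that only emerges in a combined analysis)."""
    ra, rb = _as_rooted(tree_a), _as_rooted(tree_b)
    if ra.clade != rb.clade:
        raise ValueError("trees must share one taxon set")
    scan_a = synapomorphy_scan(m, tree_a)
    scan_b = synapomorphy_scan(m, tree_b)
    syn_a = {l for ids in scan_a.counts.values() for l in ids}
    out = HiddenSynapomorphyReport()
    for clade, ids in scan_b.counts.items():
        hidden = [l for l in ids if l not in syn_a]
        if hidden:
            out.per_clade[clade] = hidden
    return out
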