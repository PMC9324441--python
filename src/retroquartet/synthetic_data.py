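"""Simulation of RI matrices and gene trees under the multispecies
coalescent, optionally on a one-reticulation species network.

The generative model mirrors the assumptions behind quartet-based RI
analysis: one haploid genome per species; gene genealogies drawn
backward in time within the branches of an ultrametric species tree
(coalescent rate k(k-1)/2 per coalescent unit for k lineages, lineages
merged at species-tree nodes); a single insertion per character, placed
on a genealogy branch with probability proportional to its length (a
constant insertion accumulation rate); presence in exactly the tip
descendants of the insertion branch.  Hemiplasy arises naturally when
the insertion lands on a genealogy branch that conflicts with the
species tree.  A reticulation redirects each lineage present in the
recipient branch at the event time to the donor branch independently
with probability gamma.  Missing data are masked independently per cell
with per-taxon rates (a simplification: real missingness is
assembly-driven and correlated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import numpy as np
import dendropy

from ._unrooted import UTree
from .rimatrix import RIMatrix, TaxonSet, MISSING, PRESENT, ABSENT

ULTRAMETRIC_TOL = 1e-6


@dataclass
class Reticulation:
    """One gene-flow edge: lineages sitting in the ``recipient`` branch
    at ``time`` (CU before present) trace the ``donor`` branch instead
    with probability ``gamma``.  Branches are named by the tip set below
    them."""

    donor: Tuple[str, ...]
    recipient: Tuple[str, ...]
    time: float
    gamma: float

    def __post_init__(self):
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if self.time < 0:
            raise ValueError("event time must be >= 0")


@dataclass
class SimulationConfig:
    species_tree: Union[str, "dendropy.Tree"]
    n_characters: int = 2000
    placement: str = "any"            # "any" | "internal"
    informative_only: bool = False
    missing_rates: Union[None, float, Dict[str, float]] = None
    reticulation: Optional[Reticulation] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.placement not in ("any", "internal"):
            raise ValueError("placement must be 'any' or 'internal'")
        if self.n_characters < 0:
            raise ValueError("n_characters must be >= 0")


class _SpNode:
    __slots__ = ("children", "label", "age", "parent")

    def __init__(self):
        self.children: List["_SpNode"] = []
        self.label: Optional[str] = None
        self.age: float = 0.0
        self.parent: Optional["_SpNode"] = None


def _parse_species_tree(tree: Union[str, "dendropy.Tree"]) -> Tuple[_SpNode, List[str]]:
    """Rooted ultrametric species tree with CU branch lengths -> node
    ages (tips at age 0)."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick",
                                 suppress_internal_node_taxa=True)

    def conv(nd, parent) -> _SpNode:
        r = _SpNode()
        r.parent = parent
        if nd.is_leaf():
            r.label = nd.taxon.label if nd.taxon is not None else nd.label
        else:
            r.children = [conv(c, r) for c in nd.child_nodes()]
        return r

    root = conv(tree.seed_node, None)

    # ages bottom-up from branch lengths on the dendropy side
    def ages(nd, sp: _SpNode) -> float:
        if nd.is_leaf():
            sp.age = 0.0
            return 0.0
        child_ages = []
        for cnd, csp in zip(nd.child_nodes(), sp.children):
            a = ages(cnd, csp)
            ln = cnd.edge.length
            if ln is None:
                raise ValueError("species tree must carry branch lengths (CU)")
            if ln < 0:
                raise ValueError("negative branch length in species tree")
            child_ages.append(a + ln)
        if max(child_ages) - min(child_ages) > ULTRAMETRIC_TOL:
            raise ValueError(
                "species tree is not ultrametric (child ages %s)"
                % child_ages)
        sp.age = sum(child_ages) / len(child_ages)
        return sp.age

    ages(tree.seed_node, root)
    labels: List[str] = []

    def tips(sp):
        if sp.label is not None:
            labels.append(sp.label)
        for c in sp.children:
            tips(c)

    tips(root)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in species tree")
    return root, sorted(labels)


class GeneNode:
    __slots__ = ("children", "label", "age", "tipset")

    def __init__(self, age: float, label: Optional[str] = None,
                 children: Optional[List["GeneNode"]] = None):
        self.age = age
        self.label = label
        self.children = children or []
        if label is not None:
            self.tipset: FrozenSet[str] = frozenset([label])
        else:
            self.tipset = frozenset().union(*(c.tipset for c in self.children))


@dataclass
class Genealogy:
    """One simulated gene genealogy, times in CU."""

    root: GeneNode

    def branches(self) -> List[Tuple[GeneNode, float]]:
        """(node, parent_age - node_age) for every non-root node."""
        out = []

        def walk(node: GeneNode):
            for c in node.children:
                out.append((c, node.age - c.age))
                walk(c)

        walk(self.root)
        return out

    def newick(self) -> str:
        def fmt(node: GeneNode, parent_age: Optional[float]) -> str:
            if node.label is not None:
                core = node.label
            else:
                core = "(" + ",".join(fmt(c, node.age)
                                      for c in node.children) + ")"
            if parent_age is None:
                return core
            return "%s:%.6f" % (core, parent_age - node.age)

        return fmt(self.root, None) + ";"

    def topology(self) -> UTree:
        return UTree.from_newick(self.newick())

    def unrooted_pairing(self, quad: Sequence[str]) -> Optional[int]:
        from ._unrooted import taxon_index, quartet_pairing
        t = self.topology()
        return quartet_pairing(t, taxon_index(t.leaf_labels()), quad)


def simulate_msc_gene_tree(config: SimulationConfig,
                           rng: Optional[np.random.Generator] = None
                           ) -> Genealogy:
    """One MSC genealogy on the configured species tree / network; one
    sampled lineage per species; deterministic given the seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    root, labels = _parse_species_tree(config.species_tree)
    ret = config.reticulation
    donor_node = recip_node = None
    if ret is not None:
        donor_node = _find_branch(root, frozenset(ret.donor))
        recip_node = _find_branch(root, frozenset(ret.recipient))
        for node, name in ((donor_node, "donor"), (recip_node, "recipient")):
            top = node.parent.age if node.parent is not None else math.inf
            if not (node.age <= ret.time < top):
                raise ValueError(
                    "reticulation time %g outside the %s branch [%g, %g)"
                    % (ret.time, name, node.age, top))
    return _simulate_one(root, rng, ret, donor_node, recip_node)


def _find_branch(root: _SpNode, tipset: FrozenSet[str]) -> _SpNode:
    stack = [root]
    while stack:
        nd = stack.pop()
        tips = _tipset(nd)
        if tips == tipset:
            return nd
        stack.extend(nd.children)
    raise ValueError("no species-tree branch above tip set %s"
                     % sorted(tipset))


def _tipset(nd: _SpNode) -> FrozenSet[str]:
    if nd.label is not None:
        return frozenset([nd.label])
    return frozenset().union(*(_tipset(c) for c in nd.children))


class _MSCSimulator:
    """Precomputed event schedule for repeated genealogy draws on one
    species tree / network."""

    def __init__(self, root: _SpNode, ret: Optional[Reticulation],
                 donor_node: Optional[_SpNode],
                 recip_node: Optional[_SpNode]):
        self.root = root
        self.ret = ret
        self.donor_key = id(donor_node) if donor_node is not None else None
        self.recip_key = id(recip_node) if recip_node is not None else None
        node_of: Dict[int, _SpNode] = {}
        depth: Dict[int, int] = {}
        tips: List[Tuple[int, str]] = []

        def walk(nd: _SpNode, d: int):
            node_of[id(nd)] = nd
            depth[id(nd)] = d
            if nd.label is not None:
                tips.append((id(nd), nd.label))
            for c in nd.children:
                walk(c, d + 1)

        walk(root, 0)
        self.node_of = node_of
        self.tips = tips
        # merges ordered by age, children before parents at equal ages;
        # the reticulation sorts before a merge at its exact time
        events: List[Tuple[float, int, int, str, int]] = [
            (nd.age, 1, -depth[id(nd)], "merge", id(nd))
            for nd in node_of.values() if nd.children]
        if ret is not None:
            events.append((ret.time, 0, 0, "flow", 0))
        events.sort(key=lambda e: e[:3])
        self.events = [(e[0], e[3], e[4]) for e in events]
        self.child_keys = {id(nd): [id(c) for c in nd.children]
                           for nd in node_of.values()}
        self.base_age = {key: nd.age for key, nd in node_of.items()}

    def run(self, rng) -> Genealogy:
        pops: Dict[int, List[GeneNode]] = {key: [] for key in self.node_of}
        for key, label in self.tips:
            pops[key] = [GeneNode(0.0, label=label)]
        clock = dict(self.base_age)

        def coalesce(key: int, t_end: float):
            lineages = pops[key]
            t = clock[key]
            k = len(lineages)
            while k >= 2:
                dt = rng.exponential(2.0 / (k * (k - 1)))
                if t + dt >= t_end:
                    break
                t += dt
                i = int(rng.integers(k))
                j = int(rng.integers(k - 1))
                if j >= i:
                    j += 1
                if i > j:
                    i, j = j, i
                merged = GeneNode(t, children=[lineages[i], lineages[j]])
                lineages[j] = lineages[-1]
                lineages[i] = merged
                lineages.pop()
                k -= 1
            clock[key] = t_end

        for when, kind, key in self.events:
            for pkey, lin in pops.items():
                if len(lin) >= 2 and clock[pkey] < when:
                    coalesce(pkey, when)
                elif clock[pkey] < when:
                    clock[pkey] = when
            if kind == "merge":
                gathered = pops[key]
                for ck in self.child_keys[key]:
                    gathered.extend(pops[ck])
                    pops[ck] = []
            else:  # gene flow
                gamma = self.ret.gamma
                stay: List[GeneNode] = []
                movers: List[GeneNode] = []
                for lin in pops[self.recip_key]:
                    (movers if rng.random() < gamma else stay).append(lin)
                pops[self.recip_key] = stay
                pops[self.donor_key].extend(movers)

        lineages = pops[id(self.root)]
        t = self.root.age
        while len(lineages) >= 2:
            k = len(lineages)
            t += rng.exponential(2.0 / (k * (k - 1)))
            i = int(rng.integers(k))
            j = int(rng.integers(k - 1))
            if j >= i:
                j += 1
            if i > j:
                i, j = j, i
            merged = GeneNode(t, children=[lineages[i], lineages[j]])
            lineages[j] = lineages[-1]
            lineages[i] = merged
            lineages.pop()
        return Genealogy(root=lineages[0])


def _simulate_one(root: _SpNode, rng, ret, donor_node, recip_node) -> Genealogy:
    return _MSCSimulator(root, ret, donor_node, recip_node).run(rng)


# ---------------------------------------------------------------------------
# RI characters


@dataclass
class SimulatedLocus:
    """Truth record for one character."""

    genealogy_newick: str
    insertion_clade: FrozenSet[str]

    @property
    def presence_set(self) -> FrozenSet[str]:
        return self.insertion_clade


def _candidate_branches(g: Genealogy, placement: str, n_tips: int):
    branches = g.branches()
    if placement == "internal":
        branches = [(node, ln) for node, ln in branches
                    if 2 <= len(node.tipset) <= n_tips - 2]
    return branches


def simulate_ri_matrix(config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None
                       ) -> Tuple[RIMatrix, List[SimulatedLocus]]:
    """Simulate a full RI matrix plus its truth record.

    Per character: one MSC genealogy; an insertion branch sampled with
    probability proportional to branch length (optionally restricted to
    branches inducing a non-trivial split, ``placement='internal'``);
    presence for the tip descendants of that branch; optional rejection
    of quartet-uninformative characters; independent per-cell missing
    masking applied after the informativeness filter."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    root, labels = _parse_species_tree(config.species_tree)
    n_tips = len(labels)
    if n_tips < 3:
        raise ValueError("need >= 3 species")
    ret = config.reticulation
    donor_node = recip_node = None
    if ret is not None:
        donor_node = _find_branch(root, frozenset(ret.donor))
        recip_node = _find_branch(root, frozenset(ret.recipient))
    sim = _MSCSimulator(root, ret, donor_node, recip_node)
    rates = _rates_vector(config.missing_rates, labels)
    cols: List[np.ndarray] = []
    truth: List[SimulatedLocus] = []
    lab_index = {lab: i for i, lab in enumerate(labels)}
    max_tries = 1000 * max(1, config.n_characters)
    tries = 0
    while len(cols) < config.n_characters:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not generate enough informative characters "
                "(placement=%r, informative_only=%r)"
                % (config.placement, config.informative_only))
        g = sim.run(rng)
        cands = _candidate_branches(g, config.placement, n_tips)
        if not cands:
            continue
        lens = [ln for _, ln in cands]
        total = sum(lens)
        if total <= 0:
            continue
        x = rng.random() * total
        pick = 0
        acc = lens[0]
        while acc < x and pick < len(lens) - 1:
            pick += 1
            acc += lens[pick]
        node = cands[pick][0]
        clade = node.tipset
        if config.informative_only:
            if not (2 <= len(clade) <= n_tips - 2):
                continue
        col = np.full(n_tips, ABSENT, dtype=np.int8)
        for lab in clade:
            col[lab_index[lab]] = PRESENT
        if rates is not None:
            mask = rng.random(n_tips) < rates
            col[mask] = MISSING
        cols.append(col)
        truth.append(SimulatedLocus(genealogy_newick=g.newick(),
                                    insertion_clade=clade))
    states = (np.column_stack(cols) if cols
              else np.zeros((n_tips, 0), dtype=np.int8))
    return RIMatrix(TaxonSet(tuple(labels)), states), truth


def _rates_vector(missing_rates, labels) -> Optional[np.ndarray]:
    if missing_rates is None:
        return None
    if isinstance(missing_rates, dict):
        return np.array([float(missing_rates.get(lab, 0.0))
                         for lab in labels])
    return np.full(len(labels), float(missing_rates))


# ---------------------------------------------------------------------------
# support-labeled gene trees


def simulate_support_gene_trees(config: SimulationConfig, n_trees: int,
                                error_rate: float = 0.0,
                                rng: Optional[np.random.Generator] = None
                                ) -> List[str]:
    """MSC genealogies with topological reconstruction error: each
    internal edge is independently hit by an NNI with probability
    ``error_rate``; node labels mimic bootstrap supports, drawn uniform
    on [0, 40] for perturbed edges and [80, 100] elsewhere."""
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    root, labels = _parse_species_tree(config.species_tree)
    ret = config.reticulation
    donor_node = recip_node = None
    if ret is not None:
        donor_node = _find_branch(root, frozenset(ret.donor))
        recip_node = _find_branch(root, frozenset(ret.recipient))
    sim = _MSCSimulator(root, ret, donor_node, recip_node)
    out: List[str] = []
    for _ in range(n_trees):
        g = sim.run(rng)
        tree = g.topology()
        tree.elen = {}
        perturbed = set()
        for (u, v) in tree.internal_edges():
            # a previous NNI may have re-homed this edge; the (u,v)
            # edge of the move itself always survives a swap
            if v not in tree.nbr[u]:
                continue
            if rng.random() < error_rate:
                _nni_in_place(tree, u, v, rng)
                perturbed.add((min(u, v), max(u, v)))
        for (u, v) in tree.internal_edges():
            key = (min(u, v), max(u, v))
            if key in perturbed:
                tree.esup[key] = float(rng.integers(0, 41))
            else:
                tree.esup[key] = float(rng.integers(80, 101))
        out.append(tree.to_newick(supports=True))
    return out


def _nni_in_place(tree: UTree, u: int, v: int, rng) -> None:
    others_u = [x for x in tree.nbr[u] if x != v]
    others_v = [x for x in tree.nbr[v] if x != u]
    b = others_u[int(rng.integers(len(others_u)))]
    c = others_v[int(rng.integers(len(others_v)))]
    tree.nbr[u].remove(b)
    tree.nbr[v].remove(c)
    tree.nbr[u].append(c)
    tree.nbr[v].append(b)
    tree.nbr[b][tree.nbr[b].index(u)] = v
    tree.nbr[c][tree.nbr[c].index(v)] = u


# a per-taxon missing-rate preset shaped like a real 48-genome avian RI
# matrix (counts of '?' per species out of 2118 characters)
AVIAN48_MISSING_COUNTS: Dict[str, int] = {
    "acan": 885, "anas": 1201, "apal": 700, "apte": 80, "bale": 242,
    "buce": 715, "caly": 1072, "capr": 431, "cari": 229, "cath": 206,
    "chae": 886, "char": 205, "chla": 409, "coli": 886, "colu": 557,
    "corv": 907, "cucu": 731, "egre": 213, "eury": 585, "falc": 290,
    "fulm": 184, "gall": 1547, "gavi": 184, "geos": 1101, "hala": 162,
    "hall": 135, "lept": 270, "mana": 833, "mele": 1644, "melo": 780,
    "mero": 746, "mesi": 596, "nest": 679, "nipp": 128, "opis": 311,
    "pele": 164, "phae": 278, "phal": 342, "phoe": 193, "pico": 1286,
    "podi": 377, "pter": 462, "pygo": 88, "stru": 1317, "taen": 1180,
    "taur": 342, "tina": 1730, "tyto": 325,
}
AVIAN48_N_CHARACTERS = 2118
AVIAN48_MISSING_RATES: Dict[str, float] = {
    k: v / AVIAN48_N_CHARACTERS for k, v in AVIAN48_MISSING_COUNTS.items()}
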