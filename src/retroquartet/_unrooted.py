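"""Lightweight unrooted leaf-labeled trees.

Internal machinery shared by the quartet engine and the tree searches.
Trees are stored as adjacency lists over integer node ids; leaves carry
string labels.  Taxon bit positions are always supplied externally (a
``{label: bit}`` mapping) so that trees over different leaf subsets can be
scored against one global taxon order.  Newick/NEXUS parsing is delegated
to dendropy; only the combinatorial operations (splits, NNI, restriction,
enumeration) are implemented here because the search moves and exact
quartet bookkeeping are the point of the package.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import dendropy

Edge = Tuple[int, int]


def _ekey(u: int, v: int) -> Edge:
    return (u, v) if u < v else (v, u)


class UTree:
    """Unrooted tree: adjacency lists + per-edge length/support."""

    __slots__ = ("nbr", "labels", "elen", "esup")

    def __init__(self) -> None:
        self.nbr: List[List[int]] = []
        self.labels: List[Optional[str]] = []
        self.elen: Dict[Edge, float] = {}
        self.esup: Dict[Edge, float] = {}

    # -- construction -----------------------------------------------------

    def _new_node(self, label: Optional[str] = None) -> int:
        self.nbr.append([])
        self.labels.append(label)
        return len(self.nbr) - 1

    def _connect(self, u: int, v: int,
                 length: Optional[float] = None,
                 support: Optional[float] = None) -> None:
        self.nbr[u].append(v)
        self.nbr[v].append(u)
        if length is not None:
            self.elen[_ekey(u, v)] = length
        if support is not None:
            self.esup[_ekey(u, v)] = support

    def _disconnect(self, u: int, v: int) -> None:
        self.nbr[u].remove(v)
        self.nbr[v].remove(u)
        self.elen.pop(_ekey(u, v), None)
        self.esup.pop(_ekey(u, v), None)

    @classmethod
    def from_dendropy(cls, tree: "dendropy.Tree") -> "UTree":
        """Convert a dendropy tree, unrooting (a bifurcating root is
        suppressed; its two child edges are merged, keeping the summed
        length and the max of the two supports)."""
        t = cls()
        node_map: Dict[object, int] = {}
        for nd in tree.preorder_node_iter():
            label = None
            if nd.is_leaf():
                label = (nd.taxon.label if nd.taxon is not None
                         else nd.label)
                if label is None:
                    raise ValueError("leaf without label in input tree")
            node_map[nd] = t._new_node(label)
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            sup = None
            if not nd.is_leaf() and nd.label is not None:
                try:
                    sup = float(nd.label)
                except ValueError:
                    sup = None
            t._connect(node_map[nd.parent_node], node_map[nd],
                       length=nd.edge.length, support=sup)
        root = node_map[tree.seed_node]
        t._suppress_degree_two(root)
        return t

    @classmethod
    def from_newick(cls, newick: str) -> "UTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
        return cls.from_dendropy(tree)

    @classmethod
    def from_split(cls, side_a: Sequence[str], side_b: Sequence[str]) -> "UTree":
        """Single-internal-edge tree separating side_a from side_b."""
        if not side_a or not side_b:
            raise ValueError("both sides of a split must be non-empty")
        t = cls()
        ua = t._new_node()
        ub = t._new_node()
        t._connect(ua, ub)
        for lab in side_a:
            t._connect(ua, t._new_node(lab))
        for lab in side_b:
            t._connect(ub, t._new_node(lab))
        # a singleton side leaves a degree-2 hub; such a "split" resolves
        # no quartets and collapses to a star
        t._suppress_degree_two()
        return t

    @classmethod
    def star(cls, labels: Sequence[str]) -> "UTree":
        t = cls()
        hub = t._new_node()
        for lab in labels:
            t._connect(hub, t._new_node(lab))
        return t

    @classmethod
    def random_topology(cls, labels: Sequence[str], rng) -> "UTree":
        """Random binary topology by stepwise addition (uniform over
        addition orders, not uniform over topologies)."""
        labels = list(labels)
        if len(labels) < 3:
            raise ValueError("need >= 3 leaves for an unrooted topology")
        order = list(labels)
        rng.shuffle(order)
        t = cls.star(order[:3])
        for lab in order[3:]:
            edges = t.edges()
            u, v = edges[rng.integers(len(edges))]
            t.insert_leaf_on_edge(lab, u, v)
        return t

    def insert_leaf_on_edge(self, label: str, u: int, v: int) -> int:
        """Subdivide edge (u,v) and attach a new leaf; returns leaf id."""
        self._disconnect(u, v)
        mid = self._new_node()
        leaf = self._new_node(label)
        self._connect(u, mid)
        self._connect(mid, v)
        self._connect(mid, leaf)
        return leaf

    # -- basic queries -----------------------------------------------------

    def nodes(self) -> Iterator[int]:
        for i, nb in enumerate(self.nbr):
            if nb:
                yield i

    def is_leaf(self, u: int) -> bool:
        return self.labels[u] is not None

    def leaf_labels(self) -> List[str]:
        return sorted(l for i, l in enumerate(self.labels)
                      if l is not None and self.nbr[i])

    def leaf_nodes(self) -> Dict[str, int]:
        return {l: i for i, l in enumerate(self.labels)
                if l is not None and self.nbr[i]}

    def edges(self) -> List[Edge]:
        out = []
        for u, nb in enumerate(self.nbr):
            for v in nb:
                if u < v:
                    out.append((u, v))
        return out

    def internal_edges(self) -> List[Edge]:
        return [(u, v) for (u, v) in self.edges()
                if not self.is_leaf(u) and not self.is_leaf(v)]

    def is_binary(self) -> bool:
        for u in self.nodes():
            d = len(self.nbr[u])
            if self.is_leaf(u):
                if d != 1:
                    return False
            elif d != 3:
                return False
        return True

    def copy(self) -> "UTree":
        t = UTree()
        t.nbr = [list(nb) for nb in self.nbr]
        t.labels = list(self.labels)
        t.elen = dict(self.elen)
        t.esup = dict(self.esup)
        return t

    # -- masks and splits --------------------------------------------------

    def directed_masks(self, index: Dict[str, int]) -> Dict[Edge, int]:
        """For every ordered pair (u,v) of adjacent nodes, the bitmask of
        leaves on the v side of edge {u,v}."""
        masks: Dict[Tuple[int, int], int] = {}

        def fill(u: int, v: int) -> int:
            key = (u, v)
            got = masks.get(key)
            if got is not None:
                return got
            masks[key] = 0  # cycle guard; trees have none but be safe
            if self.is_leaf(v):
                m = 1 << index[self.labels[v]]
            else:
                m = 0
                for w in self.nbr[v]:
                    if w != u:
                        m |= fill(v, w)
            masks[key] = m
            return m

        # iterative wrapper to avoid deep recursion on caterpillars
        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * len(self.nbr) + 100))
        try:
            for u, v in self.edges():
                fill(u, v)
                fill(v, u)
        finally:
            sys.setrecursionlimit(old)
        return masks

    def split_masks(self, index: Dict[str, int]) -> Dict[Edge, int]:
        """Non-trivial splits, one canonical mask per internal edge (the
        side not containing bit 0 of the tree's own leaf set)."""
        dm = self.directed_masks(index)
        full = 0
        for lab in self.leaf_labels():
            full |= 1 << index[lab]
        low = full & -full
        out = {}
        for (u, v) in self.internal_edges():
            m = dm[(u, v)]
            if m & low:
                m = full & ~m
            if m and m != full and bin(m).count("1") >= 2 \
                    and bin(full & ~m).count("1") >= 2:
                out[(u, v)] = m
        return out

    def has_split(self, mask: int, index: Dict[str, int]) -> bool:
        full = 0
        for lab in self.leaf_labels():
            full |= 1 << index[lab]
        want = {mask & full, full & ~(mask & full)}
        for m in self.split_masks(index).values():
            if m in want or (full & ~m) in want:
                return True
        return False

    def joining_pairs(self, index: Dict[str, int]
                      ) -> List[Tuple[List[int], List[int]]]:
        """For every unordered pair (u,v) of internal vertices, the leaf
        masks of u's neighbor subtrees away from v and of v's away from u.

        Every quartet resolved by the tree is generated exactly once: its
        two cherries attach at a unique pair of internal vertices, with the
        cherry leaves drawn from two *different* away-subtrees at each end.
        """
        dm = self.directed_masks(index)
        internal = [u for u in self.nodes() if not self.is_leaf(u)]
        # first hop from u toward any node t
        hop: Dict[int, Dict[int, int]] = {}
        for u in internal:
            h: Dict[int, int] = {}
            stack = [(u, None)]
            while stack:
                x, first = stack.pop()
                for y in self.nbr[x]:
                    if y not in h and y != u:
                        f = y if first is None else first
                        h[y] = f
                        stack.append((y, f))
            hop[u] = h
        out = []
        for i, u in enumerate(internal):
            for v in internal[i + 1:]:
                wu = hop[u][v]
                wv = hop[v][u]
                away_u = [dm[(u, x)] for x in self.nbr[u] if x != wu]
                away_v = [dm[(v, x)] for x in self.nbr[v] if x != wv]
                out.append((away_u, away_v))
        return out

    # -- topology moves ----------------------------------------------------

    def contract_edge(self, u: int, v: int) -> None:
        """Collapse internal edge (u,v), merging v into u."""
        if self.is_leaf(u) or self.is_leaf(v):
            raise ValueError("cannot contract a terminal edge")
        self._disconnect(u, v)
        for w in list(self.nbr[v]):
            length = self.elen.get(_ekey(v, w))
            sup = self.esup.get(_ekey(v, w))
            self._disconnect(v, w)
            self._connect(u, w, length=length, support=sup)
        self.nbr[v] = []
        self.labels[v] = None

    def _suppress_degree_two(self, start: Optional[int] = None) -> None:
        changed = True
        while changed:
            changed = False
            for u in list(self.nodes()):
                if not self.is_leaf(u) and len(self.nbr[u]) == 2:
                    a, b = self.nbr[u]
                    la = self.elen.get(_ekey(u, a))
                    lb = self.elen.get(_ekey(u, b))
                    sa = self.esup.get(_ekey(u, a))
                    sb = self.esup.get(_ekey(u, b))
                    self._disconnect(u, a)
                    self._disconnect(u, b)
                    length = None
                    if la is not None or lb is not None:
                        length = (la or 0.0) + (lb or 0.0)
                    sup = None
                    for s in (sa, sb):
                        if s is not None:
                            sup = s if sup is None else max(sup, s)
                    self._connect(a, b, length=length, support=sup)
                    changed = True
                elif not self.is_leaf(u) and len(self.nbr[u]) == 1:
                    # dangling internal node (after restriction)
                    (a,) = self.nbr[u]
                    self._disconnect(u, a)
                    changed = True

    def restrict(self, keep: Iterable[str]) -> "UTree":
        """Induced tree on a subset of leaves."""
        keep = set(keep)
        t = self.copy()
        for lab, node in list(t.leaf_nodes().items()):
            if lab not in keep:
                (a,) = t.nbr[node]
                t._disconnect(node, a)
                t.labels[node] = None
        t._suppress_degree_two()
        return t

    def nni_neighbors(self) -> Iterator["UTree"]:
        """The two NNI rearrangements at every internal edge (binary
        trees)."""
        for (u, v) in self.internal_edges():
            others_u = [x for x in self.nbr[u] if x != v]
            others_v = [x for x in self.nbr[v] if x != u]
            if len(others_u) != 2 or len(others_v) != 2:
                raise ValueError("NNI requires a binary tree")
            b = others_u[1]
            for c in others_v:
                t = self.copy()
                t._disconnect(u, b)
                t._disconnect(v, c)
                t._connect(u, c)
                t._connect(v, b)
                yield t

    # -- canonical form ----------------------------------------------------

    def canonical_newick(self) -> str:
        """Deterministic topology-only newick: rooted at the smallest
        leaf label, children ordered by smallest descendant label."""
        leaves = self.leaf_nodes()
        if not leaves:
            return ";"
        root_label = min(leaves)
        root = leaves[root_label]
        (anchor,) = self.nbr[root]

        def rec(u: int, parent: int) -> Tuple[str, str]:
            if self.is_leaf(u):
                return self.labels[u], self.labels[u]
            parts = [rec(w, u) for w in self.nbr[u] if w != parent]
            parts.sort(key=lambda p: p[0])
            key = parts[0][0]
            return key, "(" + ",".join(p[1] for p in parts) + ")"

        _, inner = rec(anchor, root)
        return "(%s,%s);" % (root_label, inner)

    def topology_key(self) -> str:
        return self.canonical_newick()

    def to_newick(self, lengths: bool = False, supports: bool = False,
                  root_at: Optional[str] = None) -> str:
        leaves = self.leaf_nodes()
        root_label = root_at if root_at is not None else min(leaves)
        root = leaves[root_label]
        (anchor,) = self.nbr[root]

        def fmt(u: int, parent: int) -> str:
            e = _ekey(u, parent)
            suffix = ""
            if supports and not self.is_leaf(u) and e in self.esup:
                suffix += ("%g" % self.esup[e])
            if lengths and e in self.elen:
                suffix += ":%g" % self.elen[e]
            if self.is_leaf(u):
                return self.labels[u] + (suffix if lengths else "")
            inner = ",".join(fmt(w, u) for w in self.nbr[u] if w != parent)
            return "(" + inner + ")" + suffix

        return "(%s,%s);" % (root_label, fmt(anchor, root))


def enumerate_topologies(labels: Sequence[str]) -> Iterator[UTree]:
    """All unrooted binary topologies on the labels, by recursive edge
    insertion ((2k-5)!! trees for k leaves)."""
    labels = sorted(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 leaves")

    def rec(t: UTree, remaining: List[str]) -> Iterator[UTree]:
        if not remaining:
            yield t
            return
        lab = remaining[0]
        for (u, v) in t.edges():
            t2 = t.copy()
            t2.insert_leaf_on_edge(lab, u, v)
            yield from rec(t2, remaining[1:])

    yield from rec(UTree.star(labels[:3]), labels[3:])


def taxon_index(labels: Sequence[str]) -> Dict[str, int]:
    labs = list(labels)
    if len(set(labs)) != len(labs):
        raise ValueError("duplicate taxon labels")
    return {lab: i for i, lab in enumerate(labs)}


def quartet_pairing(tree: UTree, index: Dict[str, int],
                    quad: Sequence[str]) -> Optional[int]:
    """Induced pairing of four leaves: 0 for (q0,q1|q2,q3), 1 for
    (q0,q2|q1,q3), 2 for (q0,q3|q1,q2); None if unresolved.

    Resolved iff some edge of the tree separates the cherry pairs, i.e.
    the leaf-to-leaf paths are vertex-disjoint.  Done by direct split
    inspection so it is independent of the counting kernels.
    """
    masks = [1 << index[q] for q in quad]
    full = sum(masks)
    pairings = [(masks[0] | masks[1], masks[2] | masks[3]),
                (masks[0] | masks[2], masks[1] | masks[3]),
                (masks[0] | masks[3], masks[1] | masks[2])]
    dm = tree.directed_masks(index)
    for (u, v) in tree.edges():
        side = dm[(u, v)] & full
        other = full & ~side
        for i, (a, b) in enumerate(pairings):
            if (side == a and other == b) or (side == b and other == a):
                return i
    return None


def combinations(items: Sequence, k: int):
    return itertools.combinations(items, k)
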