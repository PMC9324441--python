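"""Shared helpers for the test suite: random instances and independent
brute-force oracles kept deliberately separate from the package's own
counting kernels."""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from retroquartet._unrooted import UTree
from retroquartet.quartet_engine import InputLocus


def split_locus(lid, present: Sequence[str], absent: Sequence[str]
                ) -> InputLocus:
    return InputLocus(lid, UTree.from_split(list(present), list(absent)))


def random_split_locus(rng: np.random.Generator, labels: Sequence[str],
                       lid, min_leaves: int = 4,
                       support: Optional[float] = None) -> InputLocus:
    n = rng.integers(min_leaves, len(labels) + 1)
    leaves = list(rng.choice(labels, size=n, replace=False))
    k = int(rng.integers(1, n))
    locus = split_locus(lid, leaves[:k], leaves[k:])
    if support is not None:
        for (u, v) in locus.tree.internal_edges():  # absent for 1-vs-N
            locus.tree.esup[(min(u, v), max(u, v))] = support
    return locus


def random_gene_tree_locus(rng: np.random.Generator, labels: Sequence[str],
                           lid, min_leaves: int = 4,
                           with_supports: bool = False) -> InputLocus:
    n = int(rng.integers(min_leaves, len(labels) + 1))
    leaves = list(rng.choice(labels, size=n, replace=False))
    tree = UTree.random_topology(leaves, rng)
    if with_supports:
        for (u, v) in tree.internal_edges():
            tree.esup[(min(u, v), max(u, v))] = float(rng.integers(0, 101))
    return InputLocus(lid, tree)


def random_tree(rng: np.random.Generator, labels: Sequence[str]) -> UTree:
    return UTree.random_topology(list(labels), rng)


# --- independent Fitch oracle -------------------------------------------

# rooted trees as nested tuples: a leaf is a label string, an internal
# node a tuple of children


def random_rooted_tuple(rng: np.random.Generator, labels: Sequence[str]):
    nodes = list(labels)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append((a, b))
    return nodes[0]


def tuple_to_newick(node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(tuple_to_newick(c) for c in node) + ")"


def brute_force_fitch(node, states: Dict[str, int]) -> int:
    """Minimum changes over all internal 0/1 assignments, by explicit
    enumeration (missing leaves free)."""
    internals: List[tuple] = []

    def collect(n):
        if not isinstance(n, str):
            internals.append(n)
            for c in n:
                collect(c)

    collect(node)
    free_leaves = []

    def leaves(n):
        if isinstance(n, str):
            if n not in states:
                free_leaves.append(n)
        else:
            for c in n:
                leaves(c)

    leaves(node)
    best = None
    for bits in itertools.product((0, 1), repeat=len(internals) + len(free_leaves)):
        assign = {id(n): b for n, b in zip(internals, bits)}
        leaf_assign = dict(zip(free_leaves, bits[len(internals):]))

        def state_of(n):
            if isinstance(n, str):
                return states.get(n, leaf_assign.get(n))
            return assign[id(n)]

        changes = 0

        def walk(n):
            nonlocal changes
            if isinstance(n, str):
                return
            for c in n:
                if state_of(c) != state_of(n):
                    changes += 1
                walk(c)

        walk(node)
        if best is None or changes < best:
            best = changes
    return best
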