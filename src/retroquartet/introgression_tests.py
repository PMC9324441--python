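"""Tests for deviations from multispecies-coalescent symmetry in RI data.

Under the MSC, the two minority resolutions of a species quartet are
equally probable, so RI characters supporting them should be symmetric
up to sampling error; a skew hints at introgression.  Two tests:

* the quartet asymmetry test: an exact two-tailed binomial test of the
  two minority-resolution character counts against equal probability;
* a triplet likelihood-ratio test on the three presence patterns
  (110, 101, 011) for a species triple, comparing a polytomy (uniform
  1/3), a tree (internal length t, symmetric minors) and a two-tree
  mixture with admixture weight gamma toward the better-supported
  minority pairing.  The triplet test is a self-contained multinomial
  re-implementation in the spirit of published three-lineage insertion
  tests; its p-values are not expected to match any particular web
  tool's.

Missing data are never permitted within the taxon subset of a test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._unrooted import taxon_index, quartet_pairing
from .quartet_engine import TreeLike, as_utree
from .rimatrix import RIMatrix, MISSING, TaxonSet


def complete_character_filter(m: RIMatrix, taxa_subset: Sequence[str]
                              ) -> RIMatrix:
    """Restrict the matrix to a taxon subset, keeping only characters
    with no missing entry in the subset (the completeness requirement of
    the triplet and quartet introgression tests)."""
    labels = list(m.taxa.labels)
    try:
        rows = [labels.index(t) for t in taxa_subset]
    except ValueError as exc:
        raise ValueError("taxon %s not in the matrix" % exc.args[0].split()[0])
    sub = m.states[rows, :]
    keep = (sub != MISSING).all(axis=0)
    return RIMatrix(TaxonSet(tuple(taxa_subset)), sub[:, keep],
                    [m.locus_ids[j] for j in np.flatnonzero(keep)])


def binomial_two_tailed(k1: int, k2: int) -> float:
    """Two-tailed exact binomial p for counts (k1, k2) against equal
    probability: twice the smaller tail of Binomial(k1+k2, 1/2), capped
    at 1."""
    n = k1 + k2
    if n == 0:
        raise ValueError("no observations")
    lo = min(k1, k2)
    return min(1.0, 2.0 * float(stats.binom.cdf(lo, n, 0.5)))


@dataclass
class QuartetAsymmetryResult:
    taxa: Tuple[str, str, str, str]
    majority_pair: Tuple[str, str]       # species-tree pairing (with taxa[0])
    c1: int                              # majority-resolution characters
    minority_pairs: Tuple[Tuple[str, str], Tuple[str, str]]
    c2: int                              # larger minority count
    c3: int                              # smaller minority count
    minority_counts_by_pair: Dict[Tuple[str, str], int] = field(default_factory=dict)
    p_value: Optional[float] = None      # None when c2 + c3 == 0
    n_characters: int = 0                # complete characters examined

    @property
    def skew(self) -> float:
        tot = self.c2 + self.c3
        return (self.c2 - self.c3) / tot if tot else 0.0


def _pattern_counts_quartet(sub: np.ndarray) -> Tuple[int, int, int]:
    """Counts of the three 2v2 patterns over a 4 x L complete submatrix,
    ordered (01|23, 02|13, 03|12)."""
    informative = sub.sum(axis=0) == 2
    s = sub[:, informative]
    c0 = int(((s[0] == s[1]) & (s[2] == s[3])).sum())
    c1 = int(((s[0] == s[2]) & (s[1] == s[3])).sum())
    c2 = int(((s[0] == s[3]) & (s[1] == s[2])).sum())
    return c0, c1, c2


def quartet_asymmetry(m: RIMatrix, four_taxa: Sequence[str],
                      species_tree: TreeLike) -> QuartetAsymmetryResult:
    """Exact two-tailed binomial test of the two minority-resolution
    character counts for one species quartet; the majority resolution is
    the one the species tree displays."""
    four = tuple(four_taxa)
    if len(four) != 4 or len(set(four)) != 4:
        raise ValueError("need four distinct taxa")
    filtered = complete_character_filter(m, four)
    sub = filtered.states
    counts = _pattern_counts_quartet(sub)
    tree = as_utree(species_tree)
    index = taxon_index(tree.leaf_labels())
    pairing = quartet_pairing(tree, index, four)
    if pairing is None:
        raise ValueError("species tree does not resolve the quartet %s"
                         % (four,))
    pairs = [((four[0], four[1]), (four[2], four[3])),
             ((four[0], four[2]), (four[1], four[3])),
             ((four[0], four[3]), (four[1], four[2]))]
    c1 = counts[pairing]
    minors = [i for i in range(3) if i != pairing]
    by_pair = {pairs[i][0]: counts[i] for i in minors}
    mc = sorted((counts[i] for i in minors), reverse=True)
    c2, c3 = mc
    p = binomial_two_tailed(c2, c3) if (c2 + c3) > 0 else None
    return QuartetAsymmetryResult(
        taxa=four, majority_pair=pairs[pairing][0], c1=c1,
        minority_pairs=tuple(pairs[i][0] for i in minors),
        c2=c2, c3=c3, minority_counts_by_pair=by_pair,
        p_value=p, n_characters=filtered.n_loci)


def _adjust(pvals: List[Optional[float]], method: str) -> List[Optional[float]]:
    idx = [i for i, p in enumerate(pvals) if p is not None]
    ps = np.array([pvals[i] for i in idx], dtype=float)
    out: List[Optional[float]] = [None] * len(pvals)
    if len(ps) == 0:
        return out
    k = len(ps)
    if method == "bonferroni":
        adj = np.minimum(1.0, ps * k)
    elif method == "bh":
        order = np.argsort(ps)
        adj = np.empty(k)
        prev = 1.0
        for rank in range(k - 1, -1, -1):
            i = order[rank]
            val = min(prev, ps[i] * k / (rank + 1))
            adj[i] = val
            prev = val
    else:
        raise ValueError("unknown correction %r" % method)
    for j, i in enumerate(idx):
        out[i] = float(adj[j])
    return out


def all_quartet_asymmetry(m: RIMatrix, taxa_list: Sequence[str],
                          species_tree: TreeLike,
                          correction: str = "none") -> pd.DataFrame:
    """One asymmetry test per four-taxon subset of ``taxa_list``; raw p
    always reported, with an optional multiple-testing column."""
    if len(taxa_list) < 4:
        raise ValueError("need at least 4 taxa")
    results = [quartet_asymmetry(m, quad, species_tree)
               for quad in itertools.combinations(taxa_list, 4)]
    df = pd.DataFrame([{
        "taxa": ",".join(r.taxa),
        "majority_pair": "+".join(r.majority_pair),
        "c1": r.c1, "c2": r.c2, "c3": r.c3,
        "p_raw": r.p_value,
        "n_complete": r.n_characters,
    } for r in results])
    if correction != "none":
        df["p_adj"] = _adjust(list(df["p_raw"]), correction)
    return df


# ---------------------------------------------------------------------------
# triplet likelihood-ratio test


@dataclass
class TripletCounts:
    """Presence-pattern counts for an ordered species triple: n110 has
    the retroelement in the first two species and absent in the third,
    and so on.  Only complete characters with exactly two presences
    among the three species contribute."""

    taxa: Tuple[str, str, str]
    n110: int
    n101: int
    n011: int
    n_characters: int = 0

    @property
    def counts(self) -> Tuple[int, int, int]:
        return (self.n110, self.n101, self.n011)

    @property
    def total(self) -> int:
        return self.n110 + self.n101 + self.n011


def triplet_counts(m: RIMatrix, triple: Sequence[str]) -> TripletCounts:
    if len(triple) != 3 or len(set(triple)) != 3:
        raise ValueError("need three distinct taxa")
    filtered = complete_character_filter(m, triple)
    s = filtered.states
    two = s.sum(axis=0) == 2
    s = s[:, two]
    n110 = int(((s[0] == 1) & (s[1] == 1)).sum())
    n101 = int(((s[0] == 1) & (s[2] == 1)).sum())
    n011 = int(((s[1] == 1) & (s[2] == 1)).sum())
    return TripletCounts(taxa=tuple(triple), n110=n110, n101=n101,
                         n011=n011, n_characters=filtered.n_loci)


@dataclass
class TripletTestResult:
    counts: TripletCounts
    major_pattern: str                  # "110" / "101" / "011"
    alt_pattern: str                    # the better-supported minority
    loglik_poly: float
    loglik_tree: float
    loglik_hyb: float
    t_hat_tree: float
    t_hat_hyb: float
    gamma_hat: float
    lr_tree_poly: float
    p_tree_poly: float
    lr_hyb_tree: float
    p_hyb_tree: float
    t_saturated: bool = False           # smallest count 0: t at its cap

    @property
    def contributions(self) -> Tuple[float, float]:
        """Percent contribution of the species pairing vs the
        alternative pairing (unrooted; no donor/recipient claim)."""
        return (100.0 * (1.0 - self.gamma_hat), 100.0 * self.gamma_hat)


_T_CAP = 20.0
_PATTERNS = ("110", "101", "011")


def _multinomial_loglik(counts, probs) -> float:
    ll = 0.0
    for n, p in zip(counts, probs):
        if n == 0:
            continue
        if p <= 0.0:
            return -math.inf
        ll += n * math.log(p)
    return ll


def _tree_probs(t: float, major: int) -> Tuple[float, float, float]:
    z = math.exp(-t)
    q = z / 3.0
    out = [q, q, q]
    out[major] = 1.0 - 2.0 * z / 3.0
    return tuple(out)


def triplet_lrt(counts: TripletCounts) -> TripletTestResult:
    """Nested multinomial fits to the three triplet presence patterns.

    polytomy: uniform 1/3.  tree: the best-supported pattern gets
    p(t) = 1 - (2/3)e^(-t), the others (1/3)e^(-t); the MLE is the
    closed form t = -ln((3/2)(1 - p_major)), clamped at t = 0.
    hybridization: mixture (1-gamma) x tree(species pairing) + gamma x
    tree(alternative pairing) with shared t; two free parameters, which
    saturate the two-degree multinomial, so the fit is closed-form as
    well.  Likelihood-ratio p-values use the boundary-corrected
    (1/2)chi2_0 + (1/2)chi2_1 mixture."""
    n = list(counts.counts)
    total = sum(n)
    if total < 1:
        raise ValueError("no informative characters for the triple")
    order = sorted(range(3), key=lambda i: (-n[i], i))
    maj, alt, minr = order
    phat = [x / total for x in n]

    ll_poly = _multinomial_loglik(n, (1 / 3, 1 / 3, 1 / 3))

    # tree model: symmetric minors
    p_major_hat = max(phat[maj], 1.0 / 3.0)
    sat_tree = p_major_hat >= 1.0 - 1e-12
    t_tree = _T_CAP if sat_tree else -math.log(1.5 * (1.0 - p_major_hat))
    t_tree = min(max(t_tree, 0.0), _T_CAP)
    ll_tree = _multinomial_loglik(n, _tree_probs(t_tree, maj))

    # hybrid model saturates the simplex (ordered p1 >= p2 >= p3):
    # p3 = (1/3)e^(-t)  ->  t = -ln(3 p3);  gamma from p1.
    p3 = phat[minr]
    t_sat = p3 <= 1e-12
    t_hyb = _T_CAP if t_sat else min(-math.log(3.0 * p3), _T_CAP)
    if 1.0 - 3.0 * p3 > 1e-12:
        gamma = (1.0 - 2.0 * p3 - phat[maj]) / (1.0 - 3.0 * p3)
    else:
        gamma = 0.0
    gamma = min(max(gamma, 0.0), 1.0)
    ll_hyb = _multinomial_loglik(n, [p if p > 0 else 0.0 for p in phat])
    # guard the nesting numerically
    ll_hyb = max(ll_hyb, ll_tree)
    ll_tree = max(ll_tree, ll_poly)

    lr_tp = max(0.0, 2.0 * (ll_tree - ll_poly))
    lr_ht = max(0.0, 2.0 * (ll_hyb - ll_tree))

    def boundary_p(lr: float) -> float:
        if lr <= 1e-12:
            return 1.0
        return 0.5 * float(stats.chi2.sf(lr, 1))

    return TripletTestResult(
        counts=counts,
        major_pattern=_PATTERNS[maj], alt_pattern=_PATTERNS[alt],
        loglik_poly=ll_poly, loglik_tree=ll_tree, loglik_hyb=ll_hyb,
        t_hat_tree=t_tree, t_hat_hyb=t_hyb, gamma_hat=gamma,
        lr_tree_poly=lr_tp, p_tree_poly=boundary_p(lr_tp),
        lr_hyb_tree=lr_ht, p_hyb_tree=boundary_p(lr_ht),
        t_saturated=sat_tree or t_sat)
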