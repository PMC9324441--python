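"""Coalescent-unit branch lengths, local posterior probabilities and
anomaly-zone diagnostics from per-branch quartet tallies.

Under the multispecies coalescent the probability that a gene genealogy
matches the species-tree resolution of an internal branch of length t
(coalescent units, CU) is p(t) = 1 - (2/3) e^(-t); each alternative has
q(t) = (1/3) e^(-t).  Inverting the observed majority frequency
p_hat = n1/m gives the standard branch-length estimator
t_hat = -ln((3/2)(1 - p_hat)), and integrating the three multinomial
likelihoods against an exponential branch-length prior gives the local
posterior probability of each resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import integrate, optimize

from .quartet_engine import (BranchQuartetTally, InputLocus, TreeLike,
                             all_branch_tallies, as_utree)

SATURATION_EPS = 1e-6
DEFAULT_PRIOR_RATE = 0.5      # exponential prior rate on t, ASTRAL's default
_QUAD_UPPER = 50.0            # CU; integrand ~ e^(-rate*t) beyond any data peak


@dataclass
class BranchAnnotation:
    branch_id: str
    length_cu: Optional[float]
    flag: Optional[str]              # None | at-polytomy | saturated | undefined
    local_pp: Tuple[float, float, float]
    tally: BranchQuartetTally


def branch_length_cu(tally: BranchQuartetTally
                     ) -> Tuple[Optional[float], Optional[str]]:
    """Internal branch length in CU from the majority quartet frequency.

    Returns (length, flag): flag 'at-polytomy' when p_hat <= 1/3 (length
    clamped to 0), 'saturated' when p_hat >= 1 - eps (length capped at
    -ln(1.5 eps)), 'undefined' when m = 0 (no length)."""
    m = tally.m
    if m == 0:
        return None, "undefined"
    p_hat = tally.n1 / m
    if p_hat <= 1.0 / 3.0:
        return 0.0, "at-polytomy"
    if p_hat >= 1.0 - SATURATION_EPS:
        return -math.log(1.5 * SATURATION_EPS), "saturated"
    return -math.log(1.5 * (1.0 - p_hat)), None


def _log_integrand(t: float, n_i: int, m: int, rate: float) -> float:
    p = 1.0 - (2.0 / 3.0) * math.exp(-t)
    q = (1.0 / 3.0) * math.exp(-t)
    if p <= 0.0 or q <= 0.0:
        return -math.inf
    return (n_i * math.log(p) + (m - n_i) * math.log(q)
            + math.log(rate) - rate * t)


def _log_weight(n_i: int, m: int, rate: float) -> float:
    """log of w_i = int_0^inf p(t)^n_i q(t)^(m-n_i) rate e^(-rate t) dt,
    by adaptive quadrature around the integrand's mode."""
    res = optimize.minimize_scalar(
        lambda t: -_log_integrand(t, n_i, m, rate),
        bounds=(0.0, _QUAD_UPPER), method="bounded",
        options={"xatol": 1e-10})
    peak = float(res.x)
    log_max = _log_integrand(peak, n_i, m, rate)
    if not math.isfinite(log_max):
        log_max = _log_integrand(1e-8, n_i, m, rate)

    def f(t):
        return math.exp(_log_integrand(t, n_i, m, rate) - log_max)

    val, err = integrate.quad(f, 0.0, _QUAD_UPPER,
                              points=[peak], limit=400,
                              epsabs=1e-12, epsrel=1e-10)
    if val <= 0.0 or not math.isfinite(val):
        raise ArithmeticError(
            "local-PP quadrature failed: n_i=%d m=%d rate=%g value=%r err=%r"
            % (n_i, m, rate, val, err))
    return log_max + math.log(val)


def local_pp(tally: BranchQuartetTally,
             prior_rate: float = DEFAULT_PRIOR_RATE
             ) -> Tuple[float, float, float]:
    """Bayesian local posterior probability of the three resolutions
    around a branch, with equal 1/3 topology priors and an exponential
    branch-length prior."""
    if prior_rate <= 0.0:
        raise ValueError("prior_rate must be positive")
    m = tally.m
    counts = (tally.n1, tally.n2, tally.n3)
    if m == 0:
        return (1.0 / 3.0,) * 3
    logs = [_log_weight(n_i, m, prior_rate) for n_i in counts]
    mx = max(logs)
    w = [math.exp(l - mx) for l in logs]
    s = sum(w)
    return tuple(x / s for x in w)


def annotate_tree(species_tree: TreeLike, loci: Sequence[InputLocus],
                  prior_rate: float = DEFAULT_PRIOR_RATE):
    """Annotate every internal branch of a species tree with its quartet
    tally, CU length and local PPs.  Returns (UTree with lengths set on
    internal edges, list of BranchAnnotation)."""
    tree = as_utree(species_tree).copy()
    from ._unrooted import taxon_index
    index = taxon_index(tree.leaf_labels())
    annotations = []
    from .quartet_engine import branch_tally, canonical_side
    for (u, v), mask in tree.split_masks(index).items():
        tally = branch_tally(tree, loci, canonical_side(mask, index))
        length, flag = branch_length_cu(tally)
        pps = local_pp(tally, prior_rate)
        annotations.append(BranchAnnotation(
            branch_id=tally.branch_id, length_cu=length, flag=flag,
            local_pp=pps, tally=tally))
        key = (min(u, v), max(u, v))
        tree.elen[key] = length if length is not None else 0.0
        tree.esup[key] = round(100.0 * pps[0], 6)
    return tree, annotations


# ---------------------------------------------------------------------------
# anomaly zone


def anomaly_boundary(x: float) -> float:
    """Degnan-Rosenberg anomaly-zone boundary a(x) for a pair of adjacent
    internal branches: with the deeper branch of length x (CU), a
    descendant branch shorter than a(x) places the pair inside the
    anomaly zone (the most probable gene tree conflicts with the species
    tree).  a is strictly decreasing; a(x) <= 0 means no anomaly is
    possible below a branch of length x."""
    if x <= 0.0:
        raise ValueError("x must be positive")
    e2 = math.exp(2.0 * x)
    e3 = math.exp(3.0 * x)
    return math.log(2.0 / 3.0 + (3.0 * e2 - 2.0) / (18.0 * (e3 - e2)))


def anomaly_fixed_point(lo: float = 0.01, hi: float = 1.0,
                        xtol: float = 1e-6) -> float:
    """The branch length x* with a(x*) = x*: two equal adjacent internal
    branches of exactly this length sit on the anomaly-zone boundary."""
    return float(optimize.brentq(lambda x: anomaly_boundary(x) - x,
                                 lo, hi, xtol=xtol))


def my_to_cu(length_my: float, factor: float = 1.0) -> float:
    """Convert millions of years to coalescent units; ``factor`` is MY
    per CU (1.0 by default; 0.4 for the rough 400,000-years-per-CU avian
    conversion)."""
    if factor <= 0.0:
        raise ValueError("factor must be positive")
    return length_my / factor
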