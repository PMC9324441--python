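# Methods

This note documents the models, estimators and design choices behind
`retroquartet`, and states precisely what the simulation-backed tests do
and do not establish.

## 1. RI characters as single-bipartition gene trees

A retroelement-insertion (RI) character codes each taxon present (1),
absent (0) or missing (?).  Assuming a single insertion origin, no
precise excision and no parallel insertion, the character is the trace of
one genealogical branch: taxa descending from the insertion lineage are
present, everything else is absent, and conflicts between characters
reflect incomplete lineage sorting (hemiplasy) or gene flow, not
homoplasy.  Each character is therefore reduced to an unrooted tree with
a single internal edge separating its present side *P* from its absent
side *A*, with missing taxa removed entirely.

A character is *quartet-informative* iff both sides retain at least two
taxa after dropping missing entries (`min_side=2`): a 2+2 split is the
minimal configuration that induces any quartet.  This is the package's
reconstruction of the informativeness rule; it is the weakest condition
under which a character can contribute to the objective below.

## 2. The quartet-agreement objective

For a candidate species tree *S* and loci L₁…L_k, the score is

    Q(S) = Σ_i Σ_{q ∈ quartets(L_i)} w_i(q) · [ L_i and S induce the same
                                                resolution of q ]

summed over every four-leaf subset the locus resolves.  Unweighted
analyses use w ≡ 1; support-weighted analyses take w(q) as the minimum
support on the locus-tree edges separating the quartet's two cherries
(which reduces to the single edge support for a bipartition locus).  RI
bipartitions carry weight 100, the same trust as a 100%-bootstrap gene
tree node: the weighting scheme of the published weighted-ASTRAL method
is not printed in the literature this package follows, so the
minimum-support rule — monotone, simple, exact for one-edge loci — is
our documented approximation.

Counting is exact, never sampled.  For a bipartition locus the count of
species-tree quartets matching *P*|*A* is accumulated over pairs of
internal vertices (u, v) of *S*: every quartet resolved by a tree has a
unique pair of "joining" vertices, with its two cherry leaves drawn from
two different subtrees at each end, so

    Σ_{(u,v)} cherry_P(u→v) · cherry_A(v→u) + cherry_A(u→v) · cherry_P(v→u)

counts each matching quartet exactly once (bitmask popcounts; O(n²) per
tree, independent of locus count after aggregating identical splits).
Multi-edge gene trees are scored by explicit four-subset classification
against an LCA-depth matrix.  A separate brute-force oracle
(`brute_force_score`, split inspection per subset, ≤ 12 leaves) guards
the kernel in the test suite.

Per-branch tallies use the quadripartition rule: around an internal
branch with adjacent leaf clusters A,B | C,D, a bipartition locus S|T
adds |A∩S||B∩S||C∩T||D∩T| + |A∩T||B∩T||C∩S||D∩S| to n₁ and analogously
to n₂, n₃; EN counts the loci contributing at least one quartet.  This
EN definition coincides with the ASTRAL output for single-bipartition
loci; for multi-edge gene trees it may differ slightly from ASTRAL's
(whose exact normalization is unpublished).

## 3. Searches

* **Exhaustive** (≤ 9 taxa; 135,135 topologies at 9): the exact oracle.
  All co-optimal trees are retained; the reported tree is the
  lexicographically least canonical newick, with a tie flag.
* **Hill-climbing**: steepest-ascent NNI with seeded random restarts;
  candidate-pool trees (e.g. a reference tree, bootstrap starts) are
  used as the first starting points.  The published analyses used
  ASTRAL's internal constrained-bipartition search, which is not
  reproducible here; agreement with the exhaustive oracle on ≥ 95% of
  random 7-taxon instances (20 restarts) is the correctness surface.
  SPR moves are not implemented; restarts fill that role at the scales
  exercised.
* **Anti-constraint**: the best tree whose splits exclude a focal
  clade|rest bipartition — every candidate producing the forbidden split
  is rejected.  Used for coalescence support and linked-support reports.
* **SDPquartets**: unordered parsimony on every 4-taxon subset of the
  matrix (a complete 2v2 pattern costs 1 step on the matching topology,
  2 otherwise; characters with missing entries in the subset, or without
  a 2v2 pattern, are skipped as equal-cost).  All minimum-length
  topologies per subset become rows of an MRP matrix (pair = 1, other
  pair = 0, rest missing).  Because a quartet row costs 1 step iff the
  tree displays it, MRP treelength = #rows + #violated rows, and the MRP
  parsimony search is the same machinery maximising displayed rows.  An
  optional backbone constraint restricts the search to trees displaying
  a given topology (the outgroup/passerine device used in the avian
  study).  The published row count of 1,167,480 "species-quartets"
  equals 6·C(48,4); that multiplicity-6 encoding is unexplained in the
  source and is not reproduced.

## 4. Branch lengths and local posterior probabilities

Under the MSC, an internal branch of t coalescent units (CU) yields the
species-tree quartet resolution with probability p(t) = 1 − (2/3)e^(−t)
and each alternative with q(t) = (1/3)e^(−t).  From a branch tally
(n₁, n₂, n₃), m = n₁+n₂+n₃:

* **length**: t̂ = −ln((3/2)(1 − n₁/m)), clamped to 0 when n₁/m ≤ 1/3
  (flag `at-polytomy`), capped at −ln(1.5ε), ε = 10⁻⁶, when n₁/m ≥ 1−ε
  (flag `saturated`; a cap is more honest than ∞), undefined at m = 0.
  The estimator uses raw pooled counts (whether ASTRAL normalises
  per-locus is unstated in the source; the raw version is ours).
* **local PP**: posterior weights wᵢ ∝ ∫₀^∞ p(t)^{nᵢ} q(t)^{m−nᵢ}
  λe^{−λt} dt with equal 1/3 topology priors and exponential prior rate
  λ = 0.5 (ASTRAL's published default; the avian study does not print
  it).  The integral is evaluated in log space by adaptive quadrature on
  (0, 50] CU anchored at the integrand's mode (tolerance 10⁻⁸ relative;
  the e^{−λt} factor bounds the tail).  A 2000-node Gauss–Legendre
  oracle in the tests pins the implementation to 10⁻⁶.

The anomaly-zone boundary a(x) = ln[2/3 + (3e^{2x} − 2)/(18(e^{3x} −
e^{2x}))] is evaluated directly; its fixed point x\* with a(x\*) = x\*
(two equal adjacent internal branches exactly on the boundary) is found
by Brent bracketing on (0.01, 1) to 10⁻⁶, giving x\* = 0.156895 CU.
Printed literature values truncate this to 0.1568.  A scalar
MY→CU conversion (`my_to_cu`, default 1 MY = 1 CU, optionally 0.4 MY =
1 CU) is provided for terminal branches; terminal-length estimation
itself is out of scope.

## 5. Support and stability

* **PCS**: per-locus agreement with the optimal tree minus agreement
  with the best anti-constraint tree; the sum over loci equals the
  score difference exactly (a conservation law asserted in the tests).
  The single best anti-constraint tree found is used (whether the
  published analyses used one or several near-optimal trees is
  unstated).
* **Locus-removal index**: rank loci by PCS, remove the top locus,
  re-search (both the optimum and the anti-constraint tree are
  recomputed each step — scores shift as loci leave), stop when the
  clade drops out.  The result is an upper bound on the true minimum
  and is labeled as such; the greedy procedure matches the published
  "minimum" calculation.  If no positive-PCS locus remains, the index
  is reported unbounded.
* **Bootstrap**: loci resampled with replacement; each pseudoreplicate
  re-searched with replicate seeds spawned from the master seed, with
  the reference tree and candidate pool as starting points; clade
  frequencies mapped onto the reference tree.
* **Linked support**: for each clade, the other optimal-tree clades its
  anti-constraint tree lacks; and for a given locus-removal set, the
  clades that collapse together after re-search.

## 6. Parsimony mapping

Parsimony lengths of binary characters with missing data (state set
{0,1}) are computed by exact DP over root states, valid for
multifurcations.  For a length-1 character, the feasible change edges
are exactly the edges separating observed 1s from observed 0s; a unique
such edge makes the character an unequivocal synapomorphy.  Polarity
follows the input rooting: the derived state sits root-distally, and a
change across the root edge (both polarizations equally parsimonious)
is read as an insertion, since precise excision is rare.  Losses
(derived 0) are tallied separately and never counted as synapomorphies.
Characters whose change edge is ambiguous under missing data are
equivocal by default; the optional relaxed mode assigns them to the
shallowest feasible insertion edge (the "minimise retained ancestral
polymorphism" reading), and both counts are available rather than one
being chosen silently.  Emergent clades have zero unequivocal insertion
synapomorphies; hidden synapomorphies are unequivocal on one tree
(e.g. a combined-evidence tree) but not on another.

## 7. Introgression tests

The MSC predicts the two minority resolutions of a species quartet to be
equally frequent; skew suggests gene flow.

* **Quartet asymmetry**: exact binomial on the two minority counts
  (c₂, c₃), p = 2·P(X ≤ min(c₂,c₃)), X ~ Bin(c₂+c₃, ½), capped at 1.
  The doubled-smaller-tail convention reproduces the published p of
  0.0817 for counts 40 vs 25.  Raw p values are primary; Bonferroni and
  Benjamini–Hochberg columns are optional.
* **Triplet LRT**: the three complete-character presence patterns
  (110, 101, 011) for a species triple are fit by three nested
  multinomials — polytomy (⅓ each); tree (best-supported pattern gets
  p(t), the rest q(t); closed-form MLE); and a two-tree mixture with
  weight γ toward the better-supported minority pairing and shared t.
  The mixture's two parameters saturate the two-degree simplex, so its
  MLE is closed-form: t̂ = −ln(3p̂₃) from the smallest frequency and
  γ̂ = (1 − 2p̂₃ − p̂₁)/(1 − 3p̂₃) ∈ [0, ½].  Likelihood-ratio p values
  use the boundary-corrected ½χ²₀ + ½χ²₁ mixture.  This is a documented
  re-implementation in the spirit of the published three-lineage
  insertion tests whose formulas are not printed in the source this
  package follows; its p values are not expected to match any web
  tool's, and γ̂ is reported as the contribution of the alternative
  pairing without any donor/recipient claim (direction is not
  identifiable from unrooted counts).  The 155-topology four-lineage ML
  test is out of scope; quartet asymmetry plus the triplet LRT cover
  the 4- and 3-taxon questions at desk scale.

## 8. The simulator: what it emulates and what it does not

One haploid genome per species (matrices code one assembly per taxon).
Gene genealogies follow the standard MSC on an ultrametric species tree
with branch lengths in CU: k lineages coalesce at rate k(k−1)/2 per CU
within each branch, merging at species nodes.  A single reticulation
redirects each lineage present in the recipient branch at the event time
to the donor branch independently with probability γ; γ = 1 reproduces
the donor displayed tree in law, γ = 0 the species tree.  The simulator
is calibrated against the closed-form triplet probability
1 − (2/3)e^(−t) in the test suite.

Per character, one insertion is placed on a genealogy branch with
probability proportional to its length (a constant accumulation rate);
descendants of that branch are present, all others absent.  Branches
above the genealogy root are excluded (an insertion there would be
invariant).  `placement="internal"` restricts to branches inducing a
non-trivial split (2 ≤ descendants ≤ n−2); `informative_only` resamples
whole characters until informative, *before* masking.  Missing data are
masked independently per cell with per-taxon rates; a preset modeled on
a published 48-genome avian profile (mean 28% missing) ships with the
package.  Real missingness is assembly-driven and strongly correlated
across characters of a taxon — the independence assumption is a known
simplification, so green tests establish calibration under random
missingness only.  Gene-tree reconstruction error is modeled
topologically (independent per-edge NNI with probability `error_rate`;
perturbed edges labeled Uniform{0..40}, intact edges Uniform{80..100}),
not via sequence simulation.

Known estimator bias surfaced by this generative model: because
insertion opportunity is proportional to branch length, genealogies
concordant with a species branch (which have longer informative middle
paths) are oversampled relative to their topology frequency, so the CU
branch-length estimator of §4 is biased upward by roughly 10–20% in the
short-branch regime the tests probe (all internal branches equal, 0.05
to 0.30 CU).  The recovery test asserts the ±20% envelope reported as
"reliable" for branches < 0.3 CU; in this package's stated world the
median estimate lands inside that envelope at t = 0.05 and 0.15 and
marginally outside it at t = 0.30 (about +21%), and the test is left to
report that honestly rather than widening the band.  Users should treat
RI-based CU lengths as slight overestimates under a strict constant-rate
insertion model.

## 9. Numerical and procedural conventions

* All randomness flows through `numpy.random.Generator` seeds; searches,
  bootstraps and simulations are bit-reproducible given their seed.
* Unrooted convention throughout; rooting is display-only (and governs
  parsimony polarity in §6 where the user's rooted input is taken as
  given).
* Ties: exhaustive searches keep all co-optimal trees and flag ties;
  where one tree must be returned, the lexicographically least canonical
  newick wins.  SDPquartets encodes all tied quartet topologies as MRP
  rows.
* Gene-tree edges without a support label are treated as fully trusted
  (weight 100) and are never collapsed by `collapse_low_support`.
* The exhaustive-search cap is 9 taxa; `brute_force_score` is capped at
  12 leaves; quartet counting itself is exact at any size, with the
  O(n²)-per-tree kernel practical to ~50 taxa for scoring and small-n
  for search.

## 10. Limitations

* No multistate or polymorphic codings; symbols are fixed to {1, 0, ?}.
* No Dollo or polymorphism parsimony.
* The hill-climb is a heuristic: its guarantees are empirical (oracle
  agreement at small n), not worst-case.
* The triplet LRT's γ̂ conflates direction; its p values are asymptotic
  (boundary-corrected χ²), not exact.
* Simulated missingness is independent per cell; simulated gene-tree
  error is topological only.
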