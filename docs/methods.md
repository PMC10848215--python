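# Methods

## The permutation null model

The package randomizes an unweighted network by repeated edge swaps: pick
two existing edges (a, b) and (c, d) uniformly at random, and exchange
their targets to give (a, d) and (c, b). The exchange preserves the
endpoint multiset of all four nodes, so every node's degree — and hence
the network's degree sequence — is invariant by construction. A proposed
swap is rejected (and still counted as an attempt) if it would

* pick the same edge position twice,
* create an edge that already exists (including the degenerate identity
  proposal, where the "new" edges are the removed ones),
* create a self-loop when `allow_loops` is off,
* create an antiparallel pair {(a, b), (b, a)} in a directed network when
  `allow_antiparallel` is off, or
* create a pair in the caller's excluded set.

Excluded pairs may never *exist* in the permuted network: an original
edge in the excluded set can be swapped away but is never re-created.
This supports holdout designs where certain pairs must stay unconnected.

For undirected networks each selected edge is independently re-oriented
with probability ½ before the exchange; without this, one of the two
degree-preserving pairings {(a,d),(c,b)} and {(a,c),(b,d)} would be
unreachable. Bipartite networks use disjoint source and target index
spaces, so loops and antiparallel pairs cannot arise and both flags are
forced off. Heterogeneous (multi-edge-type) networks are permuted one
edge type at a time, so each node keeps its per-type degree.

The proposal distribution is symmetric, so the swap chain's stationary
distribution is uniform over the reachable degree-matching networks. The
test suite checks this empirically: on tiny graphs where the full
degree-matching space can be enumerated, 10,000 independent end states
pass a chi-square uniformity test at α = 0.001. The enumeration covers
the *full* degree-matching space, not just the swap-reachable component,
so a reachability gap would surface as non-uniformity there.

**Swap effort.** The default is 10·m attempted swaps. The retained
fraction of original edges approaches an asymptote as attempts grow;
`retained_fraction_curve` exposes the curve so users can verify the
plateau for denser networks, and the test suite checks that retention at
20·m is within 0.02 of retention at 10·m on a sparse 500-node graph.

**Edge membership.** Swap validity needs O(1) membership queries. A dense
boolean matrix over the source × target grid (a bitset over the row-major
pair encoding) is used up to a configurable element threshold (default
5·10⁷); beyond it a hash set of pairs caps memory.

**Determinism.** One seeded generator per permutation run; ensembles
derive independent child seeds from a master seed via `SeedSequence`.
Identical network + config + seed always reproduce the same output and
the same swap statistics.

## The edge prior

For node pair (i, j), given N permutations of which c contain the pair,
the prior is c/N, the binomial maximum-likelihood estimate of the
connection probability under the degree-only null. It is computed for
*every admissible pair* (canonical i < j pairs for undirected networks,
ordered off-diagonal pairs for directed ones, the full grid for bipartite
ones), not only observed edges. Summed over admissible pairs the priors
equal m exactly, because every permuted network contributes exactly m
edges.

**Degree grouping** (on by default) pools occurrence counts over all
pairs with the same degree pair — unordered {u, v} for undirected
unipartite networks, ordered (u, v) otherwise — and divides by the pooled
trial count. Pairs with equal degrees are exchangeable under permutation,
so each group member acts as an additional permutation, which greatly
increases the effective number of trials for common degrees. Grouping
preserves the sum-to-m identity.

**Analytical approximation.** Assuming independence between potential
edges gives the closed form

    P(u, v; m) = u·v / √((u·v)² + (m − u − v + 1)²),

with P = 0 whenever u·v = 0 (a zero-degree node can never gain an edge
under degree preservation, even though the formula's denominator is
defined there). The form is bounded in [0, 1] and monotone in each degree
throughout the feasible region u + v ≤ m + 1 (any connected pair
satisfies m ≥ u + v − 1; outside that region the formula is not monotone,
which is why the property tests restrict to it). On sparse power-law
fixtures its Spearman correlation with the Monte Carlo prior exceeds
0.999.

## Edge-prediction features

Five standard unsupervised scores, computed as dense matrices over the
admissible-pair universe: Jaccard, Adamic–Adar (common neighbors weighted
1/ln deg), resource allocation (weighted 1/deg), preferential attachment
(u·v), and random walk with restart. Conventions worth noting:

* Directed networks: the common-neighbor set is out-neighbors of the
  source ∩ in-neighbors of the target (witnesses of a path a → z → b),
  with intermediate nodes weighted by total (in + out) degree.
* RWR solves s_a = r·e_a + (1 − r)·W·s_a exactly with a dense linear
  solve (default restart r = 0.15, the conventional choice); W is
  column-stochastic, and a dangling node keeps the walker in place until
  restart (self-column), so unreachable pairs score exactly 0. The score
  of an undirected pair is the mean of the two directions; of a directed
  pair, the source-to-target stationary mass.
* Features assume loop-free networks; only preferential attachment is
  defined for bipartite networks.

## Evaluation harness

Three tasks: (1) score all admissible pairs of a network and predict its
own edges; (2) compute predictors on a uniform 70 % edge sample and
predict the held-out edges, excluding sampled-network edges from
evaluation; (3) compute predictors on one network and predict a second
network's edges over a shared node index space (nodes missing from the
training network simply have degree 0 there).

AUROC uses the Mann–Whitney rank statistic with midranks — degree-based
predictors are heavily tied, and a thresholded-curve trapezoid would
mishandle the ties. Calibration groups pairs by unique predictor value by
default (quantile binning with 20 bins is available for continuous
scores) and reports the two-component Brier decomposition; the identity
brier = calibration + refinement is exact under unique-value grouping and
is asserted to 10⁻¹⁰ in every evaluation test.

The permuted-feature baseline recomputes a feature on each of N
(default 100) permuted networks and scores it against the unpermuted
network's edges. A pure degree function (preferential attachment) is
invariant, so its baseline equals its unpermuted AUROC and the edge
prior's; structure-sensitive features drop toward the prior, and the gap
to their unpermuted AUROC measures their degree-independent signal.

## Synthetic fixtures

The generators define the study conditions for all tests:

* **configuration_model** — discrete power-law degrees P(k) ∝ k^(−γ_d)
  (default exponent 2.5; tests mostly use 2.1–2.3 with minimum degree
  2–3, the regime of heavy-tailed biomedical networks), truncated at
  n − 1, resampled until graphical (Erdős–Gallai), realized exactly via
  Havel–Hakimi, then randomized by 10·m XSwap attempts. Realization via
  construction-plus-swap guarantees a simple graph with the exact
  requested degrees; the enumeration oracle independently validates the
  randomization step.
* **bipartite / directed** — fixed edge count drawn without replacement
  over the pair grid, optionally weighted by power-law node propensities
  for heterogeneous degrees.
* **planted_partition** — community-structured graphs (4 blocks,
  p_in = 0.25, p_out = 0.01 in the tests): permutation destroys the
  community signal while preserving degree, which is what separates
  structural features from degree features.
* **degree_bias_pair** — a power-law ground truth observed twice at 30 %
  edge coverage: uniformly ("systematic") and with probability ∝
  (deg_i·deg_j)^γ ("biased", default γ used in the tests: 2). Low
  coverage is deliberate: inspection-biased literature networks cover a
  minority of true relationships, and at high coverage the two
  observations would necessarily overlap so much that no degree
  divergence could emerge. Increasing γ monotonically increases the
  Kolmogorov–Smirnov distance between the two observed degree
  distributions — the mechanism that degrades cross-network (task 3)
  transfer. Note that γ does *not* reduce the rank correlation between
  the two observations' node degrees: a degree-product bias is itself
  monotone in truth degree, so it preserves ranks even as it reshapes the
  distribution.

What these fixtures do not emulate: curation noise (false edges),
node-type-specific degree laws, or the scale of real knowledge graphs
(tests run at 200–500 nodes and ~10³ edges). Passing tests show the
machinery is correct and the qualitative phenomena — prior calibration,
degree decomposition, cross-distribution failure — are reproduced at desk
scale; absolute AUROC values on real networks will differ.

## Exact enumeration oracle

For networks whose admissible-pair universe has at most 24 pairs, every
m-subset with a matching degree sequence is enumerated, giving exact edge
priors (fraction of degree-matching graphs containing each pair). The
Monte Carlo prior is required to agree within 0.05 at ≥5000 effective
trials on every enumerable fixture; the 4-cycle (3 realizations, exact
prior 2/3 everywhere), the perfect matching on 4 nodes, a chorded path,
and a directed cycle are all covered.

## Numerical and degenerate-input choices

* Undirected edges stored canonically as (min, max); self-loops as (i, i),
  contributing 2 to the degree (endpoint-multiset accounting).
* Duplicate input edges collapse with a logged warning (unweighted model).
* Networks with m < 2 cannot be swapped: `permute` returns an unchanged
  copy with zero attempts and a warning.
* AUROC raises on single-class labels rather than returning a sentinel.
* Holdout sampling raises if the sample would be empty or complete.
* Zero-degree pairs always receive prior, approximation, and degree
  product 0.

## Known limitations

* The swap kernel is pure Python; at ~10⁶ attempts per second-scale run
  it suits networks up to ~10⁴–10⁵ edges, not massive graphs.
* Feature matrices are dense (n² memory): intended for desk-scale
  analyses, matching the admissible-pair evaluation design.
* The analytical approximation inherits its independence assumption; it
  is a ranking surrogate and mild calibration downgrade, not a substitute
  for the permutation prior when calibrated probabilities matter.
* Task 3 requires the two networks to share an integer node index space;
  mapping external identifier universes onto a shared space is left to
  the caller (`NodeIdMap` helps).
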