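# edgeprior

Degree-preserving network permutation (generalized XSwap), the **edge
prior** — the probability that two nodes are connected given only their
degrees — and an evaluation harness that decomposes any edge predictor's
performance into its degree-attributable and degree-specific parts.

## Why

Biomedical networks (protein interactions, gene regulation, drug–disease
links) have heavily skewed degree distributions, often shaped as much by
how intensively entities were studied as by biology. Edge-prediction
methods that lean on degree can then look impressive while making
nonspecific predictions — "the hub is connected to everything" — and can
fail entirely when the degree distribution shifts between training and
test data. Before trusting an edge predictor, one should know how much of
its performance a degree-only null model already achieves.

## The method

**XSwap permutation.** Two existing edges (a, b) and (c, d) are picked at
random and their targets exchanged, giving (a, d) and (c, b); the exchange
is accepted only if it creates no duplicate edge, no disallowed self-loop
or antiparallel pair, and no excluded pair. Repeating this a user-chosen
number of times (default 10·m attempts for m edges) randomizes the network
while preserving every node's degree exactly. Bipartite networks keep each
node's class and within-class degree; heterogeneous networks are permuted
one edge type at a time.

**Edge prior.** For node pair (i, j), given N permutations of which c
contain the pair, the prior is c/N — the binomial maximum-likelihood
estimate of the connection probability under the degree-only null. With
*degree grouping* (default), pairs sharing the degree pair (u, v) pool
their counts and act as extra permutations. A closed-form approximation

```
P(u, v; m) = u·v / sqrt((u·v)² + (m − u − v + 1)²)
```

is available when permutation is too expensive, along with the scaled
degree product u·v / max(u·v).

**Evaluation.** Three tasks (self-reconstruction, 70 %-holdout
reconstruction, cross-network prediction), AUROC via the tie-aware
Mann–Whitney statistic, calibration curves, and the two-component Brier
decomposition (brier = calibration + refinement). A permuted-feature
baseline recomputes any feature (Jaccard, Adamic–Adar, resource
allocation, preferential attachment, random walk with restart) on
permuted networks to measure how much of its performance is degree alone.

## Worked example

```python
from edgeprior import GeneratorSpec, generate_network, run_task

net = generate_network(GeneratorSpec(
    kind="configuration_model", n_nodes=300, exponent=2.2, min_degree=2, seed=0))
res = run_task(1, net, predictors=["prior", "approximation", "degree_product"],
               n_permutations=100, seed=1)
print(res[["predictor", "auroc", "brier", "calibration", "refinement"]])
```

prints

```
     predictor    auroc    brier  calibration  refinement
         prior 0.916985 0.017631     0.001181    0.016450
 approximation 0.916553 0.018426     0.002782    0.015645
degree_product 0.916488 0.022278     0.006263    0.016015
```

All three predictors rank node pairs almost identically (AUROC ≈ 0.917 —
on this power-law network, degree alone reconstructs most of the edge
set), but the calibration column separates them: only the permutation
edge prior is a well-calibrated probability. The `examples/` directory
walks through each capability — permutation accounting, the enumeration
oracle for exact priors on tiny graphs, features, calibration, the
degree-bias prediction tasks, and the permuted-feature baseline.

A thin CLI mirrors the library:

```bash
edgeprior synth --kind configuration_model --nodes 300 --seed 0 --output edges.tsv
edgeprior permute --input edges.tsv --output permuted.tsv --seed 0 --stats stats.json
edgeprior prior --input edges.tsv --n-permutations 100 --output prior.tsv
edgeprior evaluate --input edges.tsv --task 1 --output results.tsv
```

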