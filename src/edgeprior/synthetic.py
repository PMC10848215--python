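"""Synthetic fixtures with controlled degree structure, plus an exact oracle.

The generators emulate the degree regimes seen in biomedical networks:

* ``configuration_model`` — unipartite undirected graphs with a discrete
  power-law degree sequence (most nodes low-degree, a heavy tail of hubs),
  realized exactly (Havel–Hakimi construction, then randomized by XSwap).
* ``bipartite`` / ``directed`` — random simple networks at a target edge
  count, optionally with power-law node weights so that degree is
  heterogeneous.
* ``planted_partition`` — community-structured graphs where edges
  concentrate within blocks; permutation destroys the community signal
  while preserving degree, separating the two.
* ``degree_bias_pair`` — a ground-truth network observed twice: once by
  uniform edge sampling ("systematic") and once with probability
  proportional to the endpoint degree product raised to an inspection-bias
  exponent γ ("biased"). At γ = 0 the two coincide in distribution; larger
  γ concentrates observed edges on hubs, reproducing the situation where a
  literature-curated and a systematically derived network of the same data
  have very different degree distributions.

For tiny networks, :func:`enumerate_degree_matching_graphs` exhaustively
lists every simple network with the same degree sequence and the exact edge
prior, serving as the independent oracle for the XSwap Monte Carlo
estimate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph_io import Network, degree_sequence
from .permute import PermutationConfig, permute
from .prior import admissible_pairs

__all__ = [
    "GeneratorSpec",
    "powerlaw_degree_sequence",
    "generate_network",
    "generate_bias_pair",
    "enumerate_degree_matching_graphs",
]

_KINDS = ("configuration_model", "bipartite", "directed", "planted_partition", "degree_bias_pair")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic network draw.

    Only the fields relevant to ``kind`` are used; see
    :func:`generate_network`. ``gamma`` is the inspection-bias exponent of
    the degree-bias pair generator and ``observed_fraction`` the fraction
    of ground-truth edges each observation retains.
    """

    kind: str = "configuration_model"
    n_nodes: int = 300
    n_source: int = 100
    n_target: int = 150
    m: int | None = None
    density: float | None = None
    exponent: float = 2.5
    min_degree: int = 1
    max_degree: int | None = None
    degree: int | None = None  # constant-degree override
    heterogeneous: bool = True
    n_blocks: int = 4
    p_in: float = 0.25
    p_out: float = 0.01
    gamma: float = 0.0
    observed_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}; choose from {_KINDS}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def powerlaw_degree_sequence(
    n: int,
    exponent: float = 2.5,
    *,
    min_degree: int = 1,
    max_degree: int | None = None,
    rng: np.random.Generator | None = None,
    max_tries: int = 1000,
) -> np.ndarray:
    """Sample a graphical discrete power-law degree sequence.

    Degrees are drawn from P(k) ∝ k^(−exponent) on [min_degree, max_degree]
    (default cap n − 1) and resampled until the sequence is graphical
    (Erdős–Gallai test, via networkx) with an even sum.
    """
    rng = rng or np.random.default_rng()
    max_degree = min(max_degree or n - 1, n - 1)
    support = np.arange(min_degree, max_degree + 1)
    weights = support.astype(float) ** (-exponent)
    weights /= weights.sum()
    for _ in range(max_tries):
        degrees = rng.choice(support, size=n, p=weights)
        if degrees.sum() % 2 == 1:
            # flip one draw to restore parity without biasing the tail
            i = int(rng.integers(n))
            degrees[i] += 1 if degrees[i] < max_degree else -1
        if degrees.sum() % 2 == 0 and nx.is_graphical(sorted(degrees, reverse=True)):
            return degrees
    raise RuntimeError("failed to sample a graphical degree sequence")


def _realize_degree_sequence(degrees: np.ndarray, seed: int) -> Network:
    """Exact realization (Havel–Hakimi), randomized by 10·m XSwap attempts."""
    graph = nx.havel_hakimi_graph(list(map(int, degrees)))
    network = Network.from_edges(
        ((min(u, v), max(u, v)) for u, v in graph.edges()), n_source=len(degrees)
    )
    randomized, _ = permute(network, PermutationConfig(seed=seed))
    return randomized


def _sample_weighted_pairs(
    n_cells: int, m: int, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    probs = weights / weights.sum()
    return rng.choice(n_cells, size=m, replace=False, p=probs)


def generate_network(spec: GeneratorSpec) -> Network:
    """Draw one synthetic network. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "configuration_model":
        if spec.degree is not None:
            degrees = np.full(spec.n_nodes, spec.degree)
            if not nx.is_graphical(sorted(degrees.tolist(), reverse=True)):
                raise ValueError("constant degree sequence is not graphical")
        else:
            degrees = powerlaw_degree_sequence(
                spec.n_nodes,
                spec.exponent,
                min_degree=spec.min_degree,
                max_degree=spec.max_degree,
                rng=rng,
            )
        return _realize_degree_sequence(degrees, seed=spec.seed)
    if spec.kind == "bipartite":
        n_cells = spec.n_source * spec.n_target
        m = spec.m if spec.m is not None else int(round((spec.density or 0.1) * n_cells))
        if not 0 < m <= n_cells:
            raise ValueError("edge count out of range for bipartite grid")
        if spec.heterogeneous:
            w_src = rng.zipf(spec.exponent, spec.n_source).clip(max=spec.n_target).astype(float)
            w_tgt = rng.zipf(spec.exponent, spec.n_target).clip(max=spec.n_source).astype(float)
            weights = np.outer(w_src, w_tgt).ravel()
        else:
            weights = np.ones(n_cells)
        flat = _sample_weighted_pairs(n_cells, m, weights, rng)
        edges = [(int(f) // spec.n_target, int(f) % spec.n_target) for f in flat]
        return Network.from_edges(
            edges, n_source=spec.n_source, n_target=spec.n_target, bipartite=True
        )
    if spec.kind == "directed":
        n = spec.n_nodes
        n_cells = n * n
        m = spec.m if spec.m is not None else int(round((spec.density or 0.02) * n * (n - 1)))
        if spec.heterogeneous:
            w = rng.zipf(spec.exponent, n).clip(max=n - 1).astype(float)
            weights = np.outer(w, w).ravel()
        else:
            weights = np.ones(n_cells)
        weights[np.arange(n) * n + np.arange(n)] = 0.0  # no loops
        flat = _sample_weighted_pairs(n_cells, m, weights, rng)
        edges = [(int(f) // n, int(f) % n) for f in flat]
        return Network.from_edges(edges, n_source=n, directed=True)
    if spec.kind == "planted_partition":
        block = max(2, spec.n_nodes // spec.n_blocks)
        graph = nx.planted_partition_graph(
            spec.n_blocks, block, spec.p_in, spec.p_out, seed=int(rng.integers(2**31))
        )
        return Network.from_edges(
            ((min(u, v), max(u, v)) for u, v in graph.edges()),
            n_source=spec.n_blocks * block,
        )
    raise ValueError("use generate_bias_pair for kind='degree_bias_pair'")


def generate_bias_pair(spec: GeneratorSpec) -> tuple[Network, Network, Network]:
    """Ground truth observed twice: with inspection bias and systematically.

    Returns ``(biased, systematic, truth)``. Both observations sample
    ``round(observed_fraction * m_truth)`` truth edges without replacement:
    the systematic observation uniformly, the biased one with probability
    proportional to ``(deg_i * deg_j) ** gamma`` (truth degrees). γ = 0
    reduces the biased observation to uniform sampling.
    """
    if spec.kind != "degree_bias_pair":
        raise ValueError("spec.kind must be 'degree_bias_pair'")
    rng = np.random.default_rng(spec.seed)
    truth = _realize_degree_sequence(
        powerlaw_degree_sequence(
            spec.n_nodes, spec.exponent, min_degree=spec.min_degree,
            max_degree=spec.max_degree, rng=rng,
        ),
        seed=int(rng.integers(2**31)),
    )
    edges = sorted(truth.edges)
    n_obs = int(round(spec.observed_fraction * truth.m))
    if not 0 < n_obs <= truth.m:
        raise ValueError("observed edge count out of range")
    deg = degree_sequence(truth).source.astype(float)
    bias_weights = np.array([(deg[i] * deg[j]) ** spec.gamma for i, j in edges])
    systematic_idx = rng.choice(truth.m, size=n_obs, replace=False)
    biased_idx = rng.choice(truth.m, size=n_obs, replace=False, p=bias_weights / bias_weights.sum())
    systematic = truth.replace_edges(edges[i] for i in systematic_idx)
    biased = truth.replace_edges(edges[i] for i in biased_idx)
    return biased, systematic, truth


def enumerate_degree_matching_graphs(
    network: Network,
    *,
    allow_loops: bool = False,
    allow_antiparallel: bool = True,
    max_pairs: int = 24,
) -> tuple[list[frozenset[tuple[int, int]]], pd.DataFrame]:
    """Exhaustively enumerate all networks sharing the input's degree sequence.

    Considers every ``m``-subset of the admissible pair universe and keeps
    those whose degree sequence matches the input's exactly. For directed
    networks with ``allow_antiparallel=False`` subsets containing an
    antiparallel pair are excluded. Returns the list of edge sets and the
    exact prior table: for each admissible pair, the fraction of enumerated
    networks containing it.

    This covers the full degree-matching space, not only the states
    reachable by edge swaps; the Monte Carlo cross-check would expose any
    gap between the two. Intended for tiny fixtures only — raises if the
    admissible universe exceeds ``max_pairs``.
    """
    src_idx, tgt_idx = admissible_pairs(network, allow_loops=allow_loops)
    pairs = list(zip(src_idx.tolist(), tgt_idx.tolist()))
    if len(pairs) > max_pairs:
        raise ValueError(
            f"{len(pairs)} admissible pairs exceed the enumeration budget of {max_pairs}; "
            "use the Monte Carlo edge prior instead"
        )
    target = degree_sequence(network)
    n_src, n_tgt = network.n_source, network.n_target
    undirected = not network.directed and not network.bipartite

    matches: list[frozenset[tuple[int, int]]] = []
    contains = np.zeros(len(pairs), dtype=np.int64)
    for subset in itertools.combinations(range(len(pairs)), network.m):
        src = np.zeros(n_src, dtype=np.int64)
        tgt = np.zeros(n_tgt, dtype=np.int64)
        ok = True
        chosen = [pairs[k] for k in subset]
        if network.directed and not allow_antiparallel:
            chosen_set = set(chosen)
            if any((j, i) in chosen_set for i, j in chosen):
                continue
        for i, j in chosen:
            if undirected:
                src[i] += 1
                src[j] += 1
            else:
                src[i] += 1
                tgt[j] += 1
        if undirected:
            ok = np.array_equal(src, target.source)
        else:
            ok = np.array_equal(src, target.source) and np.array_equal(tgt, target.target)
        if ok:
            matches.append(frozenset(chosen))
            contains[list(subset)] += 1
    if not matches:
        raise RuntimeError("enumeration found no degree-matching network (including the input)")
    table = pd.DataFrame(
        {
            "source": [p[0] for p in pairs],
            "target": [p[1] for p in pairs],
            "source_degree": target.source[[p[0] for p in pairs]],
            "target_degree": target.target[[p[1] for p in pairs]],
            "prior": contains / len(matches),
        }
    )
    return matches, table
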