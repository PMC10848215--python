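"""The edge prior: probability of edge existence attributable to degree.

The edge prior for a node pair is the probability that the pair is connected
in a degree-preserving permutation of the network. It is estimated as the
fraction of N independent XSwap permutations that contain the pair — the
binomial maximum-likelihood estimate. Because permutation preserves only
degree, the prior carries no information about the network's true edges
beyond its degree sequence, which makes it a baseline predictor: any
predictor that cannot beat the edge prior is capturing degree, not specific
connectivity.

Degree grouping exploits the fact that node pairs with identical degree
pairs (u, v) are exchangeable under permutation: their occurrence counts are
pooled and treated as additional permutations, greatly increasing the
effective number of trials for common degrees. Grouping is on by default.

Two cheap degree-based companions are provided: a closed-form analytical
approximation of the prior (derived under an edge-independence assumption),

    P(u, v; m) = u*v / sqrt((u*v)^2 + (m - u - v + 1)^2),

and the scaled degree product u*v / max(u*v), both computed over the same
admissible-pair universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .graph_io import DegreeSequence, Network, degree_sequence
from .permute import PermutationConfig, permute

__all__ = [
    "admissible_pairs",
    "compute_edge_prior",
    "prior_matrix",
    "approximate_edge_prior",
    "scaled_degree_product",
]


def admissible_pairs(network: Network, *, allow_loops: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (sources, targets) of every pair that could carry an edge.

    Bipartite: the full source x target grid. Directed unipartite: all
    ordered pairs (loops only if allowed). Undirected unipartite: canonical
    pairs i < j (i <= j with loops).
    """
    if network.bipartite:
        src, tgt = np.meshgrid(
            np.arange(network.n_source), np.arange(network.n_target), indexing="ij"
        )
        return src.ravel(), tgt.ravel()
    n = network.n_source
    src, tgt = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    if network.directed:
        keep = np.ones((n, n), dtype=bool) if allow_loops else src != tgt
    else:
        keep = src <= tgt if allow_loops else src < tgt
    return src[keep], tgt[keep]


def _count_matrix(
    network: Network,
    n_permutations: int,
    permutation: PermutationConfig,
    seed: int,
) -> np.ndarray:
    """Occurrence counts per (source, target) cell over N independent permutations."""
    counts = np.zeros((network.n_source, network.n_target), dtype=np.int64)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_permutations, dtype=np.uint64)
    for k in range(n_permutations):
        rng = np.random.default_rng(int(child_seeds[k]))
        permuted, _ = permute(network, permutation, rng=rng)
        if permuted.edges:
            rows, cols = np.array(list(permuted.edges)).T
            counts[rows, cols] += 1
    return counts


def compute_edge_prior(
    network: Network,
    n_permutations: int = 100,
    *,
    degree_grouping: bool = True,
    permutation: PermutationConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Estimate the edge prior for every admissible node pair.

    Generates ``n_permutations`` independent permutations (each with its own
    seed derived from ``seed``), counts per-pair occurrences, and optionally
    pools counts over degree groups. For undirected unipartite networks the
    degree-group key is the unordered degree pair; otherwise it is ordered.

    Returns a DataFrame with columns ``source, target, source_degree,
    target_degree, count, trials, prior``: ``count`` is the (possibly
    pooled) occurrence count c, ``trials`` the effective number of trials t
    (N, or N x group size with grouping), and ``prior = c / t``.

    The priors sum to m over admissible pairs: every permuted network has
    exactly m edges, and grouping averages within groups, preserving the
    total.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    permutation = permutation or PermutationConfig()
    degrees = degree_sequence(network)
    src_idx, tgt_idx = admissible_pairs(network, allow_loops=permutation.allow_loops)
    counts = _count_matrix(network, n_permutations, permutation, seed)[src_idx, tgt_idx]

    u = degrees.source[src_idx]
    v = degrees.target[tgt_idx]
    table = pd.DataFrame(
        {
            "source": src_idx,
            "target": tgt_idx,
            "source_degree": u,
            "target_degree": v,
            "count": counts,
        }
    )
    if degree_grouping:
        if network.directed or network.bipartite:
            key_u, key_v = u, v
        else:
            key_u, key_v = np.minimum(u, v), np.maximum(u, v)
        group = pd.DataFrame({"ku": key_u, "kv": key_v, "count": counts})
        agg = group.groupby(["ku", "kv"])["count"].agg(["sum", "size"])
        pooled = agg.loc[pd.MultiIndex.from_arrays([key_u, key_v])]
        table["count"] = pooled["sum"].to_numpy()
        table["trials"] = pooled["size"].to_numpy() * n_permutations
    else:
        table["trials"] = n_permutations
    table["prior"] = table["count"] / table["trials"]
    return table


def prior_matrix(prior_table: pd.DataFrame, network: Network) -> np.ndarray:
    """Dense (n_source, n_target) matrix of priors from a prior table.

    For undirected unipartite networks both orientations of each canonical
    pair are filled.
    """
    mat = np.zeros((network.n_source, network.n_target))
    src = prior_table["source"].to_numpy()
    tgt = prior_table["target"].to_numpy()
    mat[src, tgt] = prior_table["prior"].to_numpy()
    if not network.directed and not network.bipartite:
        mat[tgt, src] = prior_table["prior"].to_numpy()
    return mat


def approximate_edge_prior(u, v, m):
    """Closed-form analytical approximation of the edge prior.

    ``P = u*v / sqrt((u*v)^2 + (m - u - v + 1)^2)`` with P = 0 whenever
    ``u*v = 0`` (a zero-degree node can never gain an edge under degree
    preservation). Accepts scalars or arrays; values lie in [0, 1] and are
    monotone nondecreasing in u and in v at fixed m.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u < 0) or np.any(v < 0) or m < 0:
        raise ValueError("degrees and edge count must be nonnegative")
    uv = u * v
    rest = m - u - v + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(uv > 0, uv / np.sqrt(uv**2 + rest**2), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def scaled_degree_product(
    network: Network,
    degrees: DegreeSequence | None = None,
    *,
    allow_loops: bool = False,
) -> pd.DataFrame:
    """Degree product u_i * v_j scaled to [0, 1] over admissible pairs.

    The scaling divides by the maximum product over admissible pairs, so the
    maximum score is 1 (attained) and the ranking is identical to the raw
    product's. All-zero degree sequences give all-zero scores.
    """
    if network.n_source == 0 or network.n_target == 0:
        raise ValueError("empty node space")
    degrees = degrees or degree_sequence(network)
    src_idx, tgt_idx = admissible_pairs(network, allow_loops=allow_loops)
    product = degrees.source[src_idx] * degrees.target[tgt_idx]
    peak = product.max() if len(product) else 0
    score = product / peak if peak > 0 else np.zeros(len(product), dtype=float)
    return pd.DataFrame(
        {
            "source": src_idx,
            "target": tgt_idx,
            "source_degree": degrees.source[src_idx],
            "target_degree": degrees.target[tgt_idx],
            "score": score,
        }
    )
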