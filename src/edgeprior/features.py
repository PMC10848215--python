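"""Degree-correlated edge-prediction features.

Five widely used unsupervised link-prediction scores, all positively
correlated with node degree to varying extents:

* Jaccard index: |Γ(a) ∩ Γ(b)| / |Γ(a) ∪ Γ(b)|.
* Adamic–Adar index: Σ_{z ∈ Γ(a) ∩ Γ(b)} 1 / ln(deg(z)).
* Resource allocation index: Σ_{z ∈ Γ(a) ∩ Γ(b)} 1 / deg(z).
* Preferential attachment index: u_a * v_b (pure degree product).
* Random walk with restart (RWR): the stationary probability of a walker
  restarting at the source being found at the target.

For directed unipartite networks the "common neighbor" set is the
intersection of the source's out-neighbors and the target's in-neighbors
(so z witnesses a path a → z → b), weighted by z's total degree. Only the
preferential attachment index is defined for bipartite networks.

All features are computed as dense score matrices; the table front-end
restricts them to the network's admissible pair universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .graph_io import Network, degree_sequence, to_adjacency
from .prior import admissible_pairs

__all__ = [
    "FEATURES",
    "jaccard_matrix",
    "adamic_adar_matrix",
    "resource_allocation_matrix",
    "preferential_attachment_matrix",
    "rwr_matrix",
    "feature_matrix",
    "compute_features",
]


def _neighbor_context(network: Network):
    """Adjacency, out/in degree vectors, and common-neighbor weights base."""
    if network.bipartite:
        raise ValueError("neighbor-set features require a unipartite network")
    adj = to_adjacency(network).astype(float)
    out_deg = adj.sum(axis=1)
    in_deg = adj.sum(axis=0)
    # weight degree of intermediate z: total degree for directed, plain degree otherwise
    total_deg = out_deg + in_deg if network.directed else out_deg
    return adj, out_deg, in_deg, total_deg


def jaccard_matrix(network: Network) -> np.ndarray:
    """Jaccard index of neighbor sets for every ordered node pair."""
    adj, out_deg, in_deg, _ = _neighbor_context(network)
    common = adj @ adj
    union = out_deg[:, None] + in_deg[None, :] - common
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(union > 0, common / union, 0.0)
    return score


def adamic_adar_matrix(network: Network) -> np.ndarray:
    """Adamic–Adar index: common neighbors weighted by 1/ln(degree)."""
    adj, _, _, total_deg = _neighbor_context(network)
    weight = np.zeros_like(total_deg)
    mask = total_deg > 1
    weight[mask] = 1.0 / np.log(total_deg[mask])
    return (adj * weight[None, :]) @ adj


def resource_allocation_matrix(network: Network) -> np.ndarray:
    """Resource allocation index: common neighbors weighted by 1/degree."""
    adj, _, _, total_deg = _neighbor_context(network)
    weight = np.zeros_like(total_deg)
    mask = total_deg > 0
    weight[mask] = 1.0 / total_deg[mask]
    return (adj * weight[None, :]) @ adj


def preferential_attachment_matrix(network: Network) -> np.ndarray:
    """Preferential attachment index: product of source and target degree."""
    degrees = degree_sequence(network)
    return np.outer(degrees.source, degrees.target).astype(float)


def rwr_matrix(network: Network, restart_probability: float = 0.15) -> np.ndarray:
    """Random-walk-with-restart scores for every node pair.

    For each source a the stationary vector s_a solves
    ``s_a = r e_a + (1 - r) W s_a`` with restart probability r and
    column-stochastic transition matrix W built from the adjacency. A
    dangling node keeps the walker in place until restart (self-column), so
    unreachable pairs score 0. Each s_a is nonnegative and sums to 1.

    The returned score for an undirected pair is the mean of s_a(b) and
    s_b(a); for a directed pair it is s_a(b) (walk from the source).
    """
    if not 0.0 < restart_probability <= 1.0:
        raise ValueError("restart_probability must be in (0, 1]")
    if network.bipartite:
        raise ValueError("RWR requires a unipartite network")
    r = restart_probability
    adj = to_adjacency(network).astype(float)
    col_sum = adj.sum(axis=0)
    walk = np.divide(adj, col_sum[None, :], out=np.zeros_like(adj), where=col_sum > 0)
    dangling = np.where(col_sum == 0)[0]
    walk[dangling, dangling] = 1.0
    n = network.n_source
    # columns of S are the stationary vectors: S = r (I - (1-r) W)^{-1}
    stationary = r * np.linalg.inv(np.eye(n) - (1.0 - r) * walk)
    score = stationary.T  # score[a, b] = s_a(b)
    if not network.directed:
        score = 0.5 * (score + score.T)
    return score


FEATURES = {
    "jaccard": jaccard_matrix,
    "adamic_adar": adamic_adar_matrix,
    "resource_allocation": resource_allocation_matrix,
    "preferential_attachment": preferential_attachment_matrix,
    "rwr": rwr_matrix,
}


def feature_matrix(network: Network, feature: str, **kwargs) -> np.ndarray:
    """Dense score matrix for one named feature."""
    try:
        fn = FEATURES[feature]
    except KeyError:
        raise ValueError(f"unknown feature {feature!r}; choose from {sorted(FEATURES)}") from None
    return fn(network, **kwargs)


def compute_features(
    network: Network,
    features: list[str] | None = None,
    *,
    restart_probability: float = 0.15,
    allow_loops: bool = False,
) -> pd.DataFrame:
    """Feature table over the network's admissible node pairs.

    Returns a DataFrame with ``source``, ``target``, and one column per
    requested feature, aligned with the pair universe used by the edge
    prior.
    """
    features = features or list(FEATURES)
    src_idx, tgt_idx = admissible_pairs(network, allow_loops=allow_loops)
    table = pd.DataFrame({"source": src_idx, "target": tgt_idx})
    for name in features:
        kwargs = {"restart_probability": restart_probability} if name == "rwr" else {}
        table[name] = feature_matrix(network, name, **kwargs)[src_idx, tgt_idx]
    return table
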