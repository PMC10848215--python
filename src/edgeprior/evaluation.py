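"""Evaluation harness: prediction tasks, AUROC, calibration, Brier decomposition.

Three prediction tasks probe how much of an edge predictor's performance is
attributable to degree:

1. **Reconstruction** — score every admissible node pair of a network and
   predict which pairs are its own edges.
2. **Sampled holdout** — sample a fraction of the edges uniformly, compute
   predictors on the sampled network, and predict the held-out edges;
   pairs that are edges of the sampled network are excluded from
   evaluation.
3. **Cross-network** — compute predictors on one network and predict the
   edges of a second network over a shared node universe (e.g., a
   literature-curated versus a systematically derived network).

Discrimination is measured by AUROC (the Mann–Whitney rank statistic with
midranks for ties — predictors here are heavily tied). Calibration is
measured by grouping pairs by predictor value and applying the 2-component
decomposition of the Brier score,

    brier = calibration + refinement,
    calibration = (1/n) Σ_g n_g (p̄_g − ō_g)²,
    refinement  = (1/n) Σ_g n_g ō_g (1 − ō_g),

which is an exact identity when groups are the unique predictor values
(p constant within each group). Lower calibration components indicate
better-calibrated probabilities.

The permuted-feature baseline computes a feature on many degree-preserving
permutations and evaluates each against the *unpermuted* network: the
resulting AUROC distribution is the feature's performance if it captured
degree only, so the gap to its unpermuted AUROC is the degree-independent
part of its performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .graph_io import Network, degree_sequence
from .permute import PermutationConfig, permute
from .prior import (
    admissible_pairs,
    approximate_edge_prior,
    compute_edge_prior,
    prior_matrix,
    scaled_degree_product,
)
from .features import FEATURES, feature_matrix

__all__ = [
    "auroc",
    "CalibrationResult",
    "calibration_curve",
    "brier_decomposition",
    "sample_holdout",
    "run_task",
    "permuted_feature_baseline",
    "PREDICTORS",
]

PREDICTORS = ("prior", "approximation", "degree_product", *FEATURES)


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann–Whitney U statistic.

    Equals the probability that a uniformly chosen positive outranks a
    uniformly chosen negative, ties counted 1/2 (midranks). Requires at
    least one positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1, False, True}:
        raise ValueError("labels must be binary")
    labels = labels.astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both a positive and a negative example")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class CalibrationResult:
    """Grouped calibration curve plus the 2-component Brier decomposition.

    ``groups`` has one row per predictor-value group with columns
    ``mean_score`` (mean predicted value p̄_g), ``observed`` (fraction of
    pairs in the group with an edge, ō_g), and ``size`` (n_g).
    """

    groups: pd.DataFrame
    brier: float
    calibration: float
    refinement: float
    grouping: str


def _group_ids(scores: np.ndarray, grouping) -> np.ndarray:
    if grouping == "unique":
        _, ids = np.unique(scores, return_inverse=True)
        return ids
    if grouping == "quantile" or isinstance(grouping, int):
        n_bins = 20 if grouping == "quantile" else grouping
        binned = pd.qcut(scores, q=n_bins, labels=False, duplicates="drop")
        return np.asarray(binned, dtype=np.int64)
    raise ValueError("grouping must be 'unique', 'quantile', or a bin count")


def calibration_curve(scores, labels, grouping="unique") -> CalibrationResult:
    """Observed edge frequency per predictor-value group.

    ``grouping='unique'`` groups by exact predictor value (matching how the
    prior repeats across same-degree pairs); ``'quantile'`` or an integer
    uses quantile bins for continuous scores. The Brier identity
    ``brier = calibration + refinement`` is exact only for unique-value
    grouping.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n = scores.size
    ids = _group_ids(scores, grouping)
    frame = pd.DataFrame({"g": ids, "score": scores, "label": labels})
    agg = frame.groupby("g").agg(
        mean_score=("score", "mean"), observed=("label", "mean"), size=("label", "size")
    )
    brier = float(np.mean((scores - labels) ** 2))
    calibration = float(
        (agg["size"] * (agg["mean_score"] - agg["observed"]) ** 2).sum() / n
    )
    refinement = float(
        (agg["size"] * agg["observed"] * (1.0 - agg["observed"])).sum() / n
    )
    return CalibrationResult(
        groups=agg.reset_index(drop=True),
        brier=brier,
        calibration=calibration,
        refinement=refinement,
        grouping=str(grouping),
    )


def brier_decomposition(scores, labels, grouping="unique") -> CalibrationResult:
    """Two-component Brier decomposition (alias of :func:`calibration_curve`)."""
    return calibration_curve(scores, labels, grouping=grouping)


def sample_holdout(
    network: Network, fraction: float, seed: int = 0
) -> tuple[Network, frozenset[tuple[int, int]]]:
    """Uniformly sample ``round(fraction * m)`` edges; hold out the rest.

    The sampled and held-out sets partition the edge set. Uniform thinning
    keeps the sampled degree distribution similar in shape to the
    original's.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be strictly between 0 and 1")
    edges = sorted(network.edges)
    k = int(round(fraction * len(edges)))
    if k == 0 or k == len(edges):
        raise ValueError("holdout sample would be empty or complete")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(edges), size=k, replace=False)
    sampled = [edges[i] for i in chosen]
    heldout = frozenset(network.edges - set(sampled))
    return network.replace_edges(sampled), heldout


def _predictor_matrix(
    name: str,
    network: Network,
    *,
    n_permutations: int,
    permutation: PermutationConfig,
    seed: int,
    restart_probability: float,
) -> np.ndarray:
    """Dense score matrix of a named predictor computed on ``network``."""
    if name == "prior":
        table = compute_edge_prior(
            network, n_permutations, permutation=permutation, seed=seed
        )
        return prior_matrix(table, network)
    if name == "approximation":
        degrees = degree_sequence(network)
        return approximate_edge_prior(
            degrees.source[:, None], degrees.target[None, :], network.m
        )
    if name == "degree_product":
        table = scaled_degree_product(network)
        mat = np.zeros((network.n_source, network.n_target))
        src = table["source"].to_numpy()
        tgt = table["target"].to_numpy()
        mat[src, tgt] = table["score"].to_numpy()
        if not network.directed and not network.bipartite:
            mat[tgt, src] = table["score"].to_numpy()
        return mat
    if name == "rwr":
        return feature_matrix(network, "rwr", restart_probability=restart_probability)
    return feature_matrix(network, name)


def run_task(
    task: int,
    network: Network,
    *,
    second: Network | None = None,
    predictors=("prior", "approximation", "degree_product"),
    holdout_fraction: float = 0.7,
    n_permutations: int = 100,
    permutation: PermutationConfig | None = None,
    restart_probability: float = 0.15,
    grouping="unique",
    seed: int = 0,
) -> pd.DataFrame:
    """Run one prediction task for a set of predictors.

    Task 1 reconstructs ``network`` from itself; task 2 reconstructs it
    from a uniform ``holdout_fraction`` edge sample (sampled-network edges
    are excluded from evaluation); task 3 computes predictors on
    ``network`` and predicts the edges of ``second``, which must share the
    node index spaces.

    Returns a tidy table with columns ``task, predictor, auroc, brier,
    calibration, refinement, n_pairs, n_positive``.
    """
    permutation = permutation or PermutationConfig()
    if task not in (1, 2, 3):
        raise ValueError("task must be 1, 2, or 3")
    if task == 3:
        if second is None:
            raise ValueError("task 3 requires a second network")
        if (second.n_source, second.n_target) != (network.n_source, network.n_target):
            raise ValueError("task 3 networks must share their node index spaces")

    src_idx, tgt_idx = admissible_pairs(network, allow_loops=permutation.allow_loops)
    if task == 1:
        train = network
        labels = np.array([network.has_edge(i, j) for i, j in zip(src_idx, tgt_idx)])
    elif task == 2:
        train, heldout = sample_holdout(network, holdout_fraction, seed=seed)
        keep = np.array([not train.has_edge(i, j) for i, j in zip(src_idx, tgt_idx)])
        src_idx, tgt_idx = src_idx[keep], tgt_idx[keep]
        labels = np.array([(i, j) in heldout for i, j in zip(src_idx, tgt_idx)])
    else:
        train = network
        labels = np.array([second.has_edge(i, j) for i, j in zip(src_idx, tgt_idx)])

    if labels.all() or not labels.any():
        raise ValueError("evaluation pairs contain a single class; AUROC is undefined")

    rows = []
    for name in predictors:
        mat = _predictor_matrix(
            name,
            train,
            n_permutations=n_permutations,
            permutation=permutation,
            seed=seed,
            restart_probability=restart_probability,
        )
        scores = mat[src_idx, tgt_idx]
        in_unit = scores.min() >= 0.0 and scores.max() <= 1.0
        cal = calibration_curve(scores, labels, grouping=grouping) if in_unit else None
        rows.append(
            {
                "task": task,
                "predictor": name,
                "auroc": auroc(scores, labels),
                "brier": cal.brier if cal else np.nan,
                "calibration": cal.calibration if cal else np.nan,
                "refinement": cal.refinement if cal else np.nan,
                "n_pairs": len(labels),
                "n_positive": int(labels.sum()),
            }
        )
    return pd.DataFrame(rows)


def permuted_feature_baseline(
    network: Network,
    feature: str,
    n_permutations: int = 100,
    *,
    permutation: PermutationConfig | None = None,
    restart_probability: float = 0.15,
    seed: int = 0,
) -> np.ndarray:
    """AUROC distribution of a feature computed on permuted networks.

    Each of ``n_permutations`` degree-preserving permutations gets the
    feature recomputed on it and evaluated against the *unpermuted*
    network's edges (task-1 labels). The distribution shows how the feature
    would perform if it captured only degree; comparing with the feature's
    unpermuted AUROC decomposes its performance into degree-attributable
    and degree-specific parts.
    """
    permutation = permutation or PermutationConfig()
    src_idx, tgt_idx = admissible_pairs(network, allow_loops=permutation.allow_loops)
    labels = np.array([network.has_edge(i, j) for i, j in zip(src_idx, tgt_idx)])
    kwargs = {"restart_probability": restart_probability} if feature == "rwr" else {}
    child_seeds = np.random.SeedSequence(seed).generate_state(n_permutations, dtype=np.uint64)
    values = np.empty(n_permutations)
    for k in range(n_permutations):
        rng = np.random.default_rng(int(child_seeds[k]))
        permuted, _ = permute(network, permutation, rng=rng)
        scores = feature_matrix(permuted, feature, **kwargs)[src_idx, tgt_idx]
        values[k] = auroc(scores, labels)
    return values
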