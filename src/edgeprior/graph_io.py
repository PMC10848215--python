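"""Network data model, identifier mapping, and edge-list / adjacency I/O.

Networks are unweighted and stored as sets of integer index pairs. Indices
are 0-based and contiguous within each node space; external identifiers are
handled only at the I/O boundary through :class:`NodeIdMap`.

Conventions
-----------
* Undirected unipartite edges are stored in canonical orientation
  ``(min(i, j), max(i, j))``; a self-loop is ``(i, i)``.
* Directed edges are stored as ``(source, target)``; the antiparallel pair
  ``(j, i)`` is a distinct edge.
* Bipartite networks use two disjoint index spaces: an edge ``(i, j)`` has
  ``i`` in the source space and ``j`` in the target space, so loops and
  antiparallel pairs cannot exist by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NodeIdMap",
    "DegreeSequence",
    "canonical_edge",
    "load_edge_list",
    "write_edge_list",
    "degree_sequence",
    "to_adjacency",
    "from_adjacency",
    "write_mtx",
    "load_mtx",
]


def canonical_edge(i: int, j: int, *, directed: bool, bipartite: bool) -> tuple[int, int]:
    """Return the stored orientation of an edge between indices ``i`` and ``j``."""
    if directed or bipartite or i <= j:
        return (i, j)
    return (j, i)


@dataclass(frozen=True)
class Network:
    """An unweighted network over typed integer node spaces.

    Parameters
    ----------
    n_source, n_target
        Sizes of the source and target node spaces. Equal for unipartite
        networks (and ``n_target`` defaults to ``n_source``).
    edges
        Set of ``(source_index, target_index)`` pairs in canonical
        orientation.
    directed
        Whether edge orientation is meaningful (unipartite only).
    bipartite
        Whether source and target indices live in disjoint spaces.
    """

    n_source: int
    n_target: int
    edges: frozenset[tuple[int, int]]
    directed: bool = False
    bipartite: bool = False

    def __post_init__(self) -> None:
        if self.bipartite and self.directed:
            raise ValueError("bipartite networks have a fixed orientation; use directed=False")
        if self.n_source < 0 or self.n_target < 0:
            raise ValueError("node counts must be nonnegative")
        if not self.bipartite and self.n_source != self.n_target:
            raise ValueError("unipartite networks require n_source == n_target")
        for i, j in self.edges:
            if not (0 <= i < self.n_source and 0 <= j < self.n_target):
                raise ValueError(f"edge ({i}, {j}) outside node spaces")
            if self.bipartite is False and self.directed is False and i > j:
                raise ValueError(f"undirected edge ({i}, {j}) not in canonical (min, max) form")

    @property
    def m(self) -> int:
        """Total number of edges."""
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        """Number of nodes across both spaces (n_source for unipartite)."""
        return self.n_source if not self.bipartite else self.n_source + self.n_target

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[int, int]],
        *,
        n_source: int | None = None,
        n_target: int | None = None,
        directed: bool = False,
        bipartite: bool = False,
    ) -> "Network":
        """Build a network from raw pairs, canonicalizing and deduplicating."""
        edges = list(edges)
        canon = frozenset(
            canonical_edge(i, j, directed=directed, bipartite=bipartite) for i, j in edges
        )
        if n_source is None:
            n_source = 1 + max((e[0] for e in edges), default=-1)
            if not bipartite:
                n_source = max(n_source, 1 + max((e[1] for e in edges), default=-1))
        if n_target is None:
            n_target = n_source if not bipartite else 1 + max((e[1] for e in edges), default=-1)
        return cls(n_source, n_target, canon, directed=directed, bipartite=bipartite)

    def has_edge(self, i: int, j: int) -> bool:
        return canonical_edge(i, j, directed=self.directed, bipartite=self.bipartite) in self.edges

    def replace_edges(self, edges: Iterable[tuple[int, int]]) -> "Network":
        """A copy of this network with the same node spaces but new edges."""
        return Network.from_edges(
            edges,
            n_source=self.n_source,
            n_target=self.n_target,
            directed=self.directed,
            bipartite=self.bipartite,
        )


@dataclass
class NodeIdMap:
    """Bijection between external identifiers and integer indices.

    One map per node space; unipartite networks share a single space and the
    target-side accessors simply mirror the source side.
    """

    source_forward: dict[str, int] = field(default_factory=dict)
    target_forward: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self._source_reverse = {v: k for k, v in self.source_forward.items()}
        if self.target_forward is None:
            self._target_reverse = self._source_reverse
        else:
            self._target_reverse = {v: k for k, v in self.target_forward.items()}

    def add_source(self, identifier: str) -> int:
        idx = self.source_forward.get(identifier)
        if idx is None:
            idx = len(self.source_forward)
            self.source_forward[identifier] = idx
            self._source_reverse[idx] = identifier
        return idx

    def add_target(self, identifier: str) -> int:
        if self.target_forward is None:
            return self.add_source(identifier)
        idx = self.target_forward.get(identifier)
        if idx is None:
            idx = len(self.target_forward)
            self.target_forward[identifier] = idx
            self._target_reverse[idx] = identifier
        return idx

    def source_id(self, index: int) -> str:
        return self._source_reverse[index]

    def target_id(self, index: int) -> str:
        return self._target_reverse[index]


@dataclass(frozen=True)
class DegreeSequence:
    """Per-node degree vectors: ``source[i]`` = u_i, ``target[j]`` = v_j.

    For undirected unipartite networks the two vectors are identical (the
    same array object).
    """

    source: np.ndarray
    target: np.ndarray


def degree_sequence(network: Network) -> DegreeSequence:
    """Count source and target degrees from the edge set.

    A self-loop contributes 2 to its node's degree in the undirected case,
    matching endpoint-multiset accounting (each edge has two endpoints).
    """
    if network.directed or network.bipartite:
        src = np.zeros(network.n_source, dtype=np.int64)
        tgt = np.zeros(network.n_target, dtype=np.int64)
        for i, j in network.edges:
            src[i] += 1
            tgt[j] += 1
        return DegreeSequence(src, tgt)
    deg = np.zeros(network.n_source, dtype=np.int64)
    for i, j in network.edges:
        deg[i] += 1
        deg[j] += 1
    return DegreeSequence(deg, deg)


def load_edge_list(
    path: str | Path,
    *,
    directed: bool = False,
    bipartite: bool = False,
) -> tuple[Network, NodeIdMap]:
    """Read a two-column TSV edge list, assigning indices by first appearance.

    Lines beginning with ``#`` are ignored. Duplicate edges (including the
    reverse orientation of an undirected edge) collapse silently with a
    logged count. Fields may be separated by any whitespace.

    Raises
    ------
    ValueError
        On a malformed line (not exactly two fields), or a self-loop in a
        bipartite file.
    """
    id_map = NodeIdMap(target_forward={} if bipartite else None)
    raw_edges: list[tuple[int, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, found {len(fields)}")
            src, tgt = fields
            if bipartite and src == tgt:
                raise ValueError(
                    f"{path}:{lineno}: identifier {src!r} used as both source and target "
                    "of one edge in a bipartite network"
                )
            raw_edges.append((id_map.add_source(src), id_map.add_target(tgt)))
    network = Network.from_edges(
        raw_edges,
        n_source=len(id_map.source_forward),
        n_target=len(id_map.target_forward) if bipartite else None,
        directed=directed,
        bipartite=bipartite,
    )
    n_dup = len(raw_edges) - network.m
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, n_dup)
    return network, id_map


def write_edge_list(
    network: Network,
    path: str | Path,
    id_map: NodeIdMap | None = None,
) -> None:
    """Write a TSV edge list, mapping indices back through ``id_map`` if given."""
    with open(path, "w") as handle:
        for i, j in sorted(network.edges):
            if id_map is not None:
                handle.write(f"{id_map.source_id(i)}\t{id_map.target_id(j)}\n")
            else:
                handle.write(f"{i}\t{j}\n")


def to_adjacency(network: Network, *, sparse: bool = False):
    """0/1 adjacency matrix of shape ``(n_source, n_target)``.

    Symmetric for undirected unipartite networks (both triangles filled).
    """
    if network.edges:
        rows, cols = np.array(sorted(network.edges)).T
    else:
        rows = cols = np.array([], dtype=np.int64)
    shape = (network.n_source, network.n_target)
    mat = scipy.sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=shape
    )
    if not network.directed and not network.bipartite:
        off = rows != cols
        sym = scipy.sparse.coo_matrix(
            (np.ones(off.sum(), dtype=np.int8), (cols[off], rows[off])), shape=shape
        )
        mat = (mat + sym).tocoo()
    if sparse:
        return mat.tocsr()
    return np.asarray(mat.todense())


def from_adjacency(
    matrix,
    *,
    directed: bool = False,
    bipartite: bool = False,
) -> Network:
    """Inverse of :func:`to_adjacency` (up to the symmetric-storage convention)."""
    mat = scipy.sparse.coo_matrix(matrix)
    n_source, n_target = mat.shape
    edges = [(int(i), int(j)) for i, j, v in zip(mat.row, mat.col, mat.data) if v]
    return Network.from_edges(
        edges, n_source=n_source, n_target=n_target, directed=directed, bipartite=bipartite
    )


def write_mtx(network: Network, path: str | Path) -> None:
    """Write the adjacency matrix in MatrixMarket coordinate format."""
    scipy.io.mmwrite(str(path), to_adjacency(network, sparse=True))


def load_mtx(path: str | Path, *, directed: bool = False, bipartite: bool = False) -> Network:
    """Read an adjacency matrix in MatrixMarket format."""
    return from_adjacency(scipy.io.mmread(str(path)), directed=directed, bipartite=bipartite)
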