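"""Efficiency metrics on binary undirected brain networks.

Global efficiency is the mean inverse shortest-path length over ordered
node pairs,

    E_glob(G) = 1/(N(N-1)) * sum_{i != j} 1/d_ij,

nodal efficiency of node i is the same mean restricted to paths from i,

    E_nod(i) = 1/(N-1) * sum_{j != i} 1/d_ij,

and local efficiency averages, over nodes, the global efficiency of the
subgraph induced on each node's neighbors (node i itself excluded),

    E_loc(G) = 1/N * sum_i E_glob(G_i).

Disconnected pairs contribute 1/inf := 0, the standard convention for
efficiency on possibly fragmented graphs; nodes with fewer than two
neighbors contribute 0 to E_loc.  Distances come from an all-sources
breadth-first search; tests cross-check against a Floyd-Warshall oracle.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .connectivity import BinaryNetwork

__all__ = [
    "EfficiencyResult",
    "shortest_path_lengths",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "efficiency_metrics",
]


@dataclasses.dataclass
class EfficiencyResult:
    """Per-subject efficiency summary at a stated sparsity."""

    subject_id: str
    e_glob: float
    e_loc: float
    e_nod: np.ndarray  # length N
    sparsity: float | None = None


def _as_adjacency(network: BinaryNetwork | np.ndarray) -> np.ndarray:
    adj = network.adjacency if isinstance(network, BinaryNetwork) else network
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    adj = (adj != 0).astype(bool)
    if adj.diagonal().any():
        raise ValueError("self-loops are not allowed")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric (undirected)")
    return adj


def shortest_path_lengths(network: BinaryNetwork | np.ndarray) -> np.ndarray:
    """All-pairs hop distances by simultaneous breadth-first search.

    Returns an (N, N) float matrix with 0 on the diagonal and ``inf`` for
    unreachable pairs.
    """
    adj = _as_adjacency(network)
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    visited = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    d = 0
    while frontier.any():
        d += 1
        # Expand every source's frontier one hop in a single boolean matmul.
        frontier = (frontier @ adj) & ~visited
        dist[frontier] = d
        visited |= frontier
    return dist


def global_efficiency(network: BinaryNetwork | np.ndarray) -> float:
    adj = _as_adjacency(network)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    inv = _inverse_distances(adj)
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(
    network: BinaryNetwork | np.ndarray, node: int | None = None
) -> np.ndarray | float:
    """Per-node mean inverse distance to all other nodes.

    With ``node=None`` returns the full length-N vector; otherwise the
    scalar for that 0-based node index.
    """
    adj = _as_adjacency(network)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency requires at least 2 nodes")
    e_nod = _inverse_distances(adj).sum(axis=1) / (n - 1)
    if node is None:
        return e_nod
    return float(e_nod[node])


def local_efficiency(network: BinaryNetwork | np.ndarray) -> float:
    adj = _as_adjacency(network)
    n = adj.shape[0]
    if n < 1:
        raise ValueError("local efficiency requires at least 1 node")
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue  # fewer than 2 neighbors: no subgraph pairs, contributes 0
        sub = adj[np.ix_(nbrs, nbrs)]
        total += global_efficiency(sub)
    return total / n


def _inverse_distances(adj: np.ndarray) -> np.ndarray:
    dist = shortest_path_lengths(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(dist)] = 0.0
    return inv


def efficiency_metrics(
    network: BinaryNetwork, subject_id: str | None = None
) -> EfficiencyResult:
    """Compute E_glob, E_loc and the E_nod vector for one binary network."""
    e_nod = nodal_efficiency(network)
    return EfficiencyResult(
        subject_id=subject_id or getattr(network, "subject_id", ""),
        e_glob=float(np.mean(e_nod)),  # identity: E_glob is the mean of E_nod
        e_loc=local_efficiency(network),
        e_nod=np.asarray(e_nod),
        sparsity=getattr(network, "sparsity", None),
    )
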