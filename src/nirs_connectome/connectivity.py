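"""Functional connectivity: Pearson matrices, Fisher z, sparsity thresholding.

Each subject's channels x channels Pearson correlation matrix is
variance-stabilized with Fisher's r-to-z transform (z = atanh r) and then
binarized at a fixed network sparsity S — the fraction of realized edges
over the N(N-1)/2 possible pairs — by keeping the most strongly positive
z values.  Group statistics downstream operate on the z values; each
subject's binary network comes from that subject's own matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .layout_io import HemoglobinRecording

__all__ = [
    "ConnectivityMatrix",
    "BinaryNetwork",
    "pearson_matrix",
    "fisher_z",
    "binarize_at_sparsity",
    "edge_count_at_sparsity",
]

# Clamp |r| just below 1 so atanh stays finite for numerically perfect
# correlations (duplicated channels, degenerate simulations).
_R_CLAMP = 1.0 - 1e-15


@dataclasses.dataclass
class ConnectivityMatrix:
    """Symmetric Pearson r and Fisher z matrices for one subject.

    The diagonal is undefined by convention and stored as NaN.
    """

    subject_id: str
    r: np.ndarray
    z: np.ndarray

    @property
    def n_channels(self) -> int:
        return int(self.r.shape[0])


@dataclasses.dataclass
class BinaryNetwork:
    """Unweighted undirected adjacency at a stated sparsity."""

    adjacency: np.ndarray  # (N, N) 0/1, zero diagonal
    sparsity: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return int(self.adjacency.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def pearson_matrix(recording: HemoglobinRecording) -> ConnectivityMatrix:
    """Pearson correlation between every pair of channel time series."""
    data = recording.data
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    sd = data.std(axis=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        ids = recording.channel_ids[const].tolist()
        raise ValueError(f"constant channel(s) {ids}: correlation undefined")
    r = np.corrcoef(data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    z = np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))
    np.fill_diagonal(r, np.nan)
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(subject_id=recording.subject_id, r=r, z=z)


def fisher_z(r):
    """Fisher's r-to-z transform, z = atanh(r), elementwise.

    Accepts scalars or arrays with |r| <= 1; exact +-1 is clamped just
    inside the open interval so the result stays finite.
    """
    arr = np.asarray(r, dtype=float)
    if np.nanmax(np.abs(arr)) > 1:
        raise ValueError("|r| must not exceed 1")
    out = np.arctanh(np.clip(arr, -_R_CLAMP, _R_CLAMP))
    if np.isscalar(r) or arr.ndim == 0:
        return float(out)
    return out


def edge_count_at_sparsity(n_nodes: int, sparsity: float) -> int:
    return int(np.rint(sparsity * n_nodes * (n_nodes - 1) / 2))


def binarize_at_sparsity(
    matrix: ConnectivityMatrix | np.ndarray,
    sparsity: float = 0.2,
    rank_by_magnitude: bool = False,
) -> BinaryNetwork:
    """Threshold a connectivity matrix into a binary network of fixed sparsity.

    The round(S * N(N-1)/2) node pairs with the largest z become edges.
    Ranking is on signed z by default (most positive first), so negative
    correlations fall to the bottom; ``rank_by_magnitude`` ranks |z|
    instead.  Ties break lexicographically on the (i, j) pair, i < j, so
    the result is deterministic and invariant to positive rescaling of z.
    """
    if isinstance(matrix, ConnectivityMatrix):
        subject_id = matrix.subject_id
        z = matrix.z
    else:
        subject_id = ""
        z = np.asarray(matrix, dtype=float)
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    n = z.shape[0]
    k = edge_count_at_sparsity(n, sparsity)
    if k < 1:
        raise ValueError(
            f"sparsity {sparsity} yields zero edges on {n} nodes"
        )
    iu, ju = np.triu_indices(n, k=1)
    vals = z[iu, ju]
    key = np.abs(vals) if rank_by_magnitude else vals
    # lexsort: last key is primary; then smaller i, then smaller j.
    order = np.lexsort((ju, iu, -key))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, sparsity=sparsity, subject_id=subject_id)
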