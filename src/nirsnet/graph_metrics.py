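"""Binary network construction and the three graph indices.

A correlation matrix is binarized at a threshold T: an (undirected, simple)
edge exists between channels i ≠ j iff |r_ij| >= T — note the absolute value,
so strong negative correlations also create edges.  On the binary network the
indices are

* C — network clustering coefficient: mean over all N nodes of
  C_i = E_i / (k_i (k_i - 1) / 2), where E_i counts edges among the neighbors
  of node i and k_i is its degree; nodes with k_i < 2 contribute C_i = 0.
* L — average path length: mean shortest-path (geodesic) distance over node
  pairs.  For disconnected graphs the mean runs over *reachable* pairs only
  and the ``connected`` flag records the situation.
* K_mean — average node degree, 2E/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .connectivity import CorrelationMatrix

__all__ = [
    "BinaryNetwork",
    "NetworkMetrics",
    "binarize",
    "clustering_coefficient",
    "average_path_length",
    "average_degree",
    "is_connected",
    "network_metrics",
]


@dataclass
class BinaryNetwork:
    """Undirected simple graph as a 0/1 adjacency matrix (zero diagonal)."""

    labels: list[str]
    adjacency: np.ndarray
    threshold: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def validate(self) -> None:
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if self.labels and len(self.labels) != a.shape[0]:
            raise ValueError("labels must match adjacency size")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")


def binarize(matrix: CorrelationMatrix, threshold: float) -> BinaryNetwork:
    """Edge iff |r| >= threshold (boundary included), no self-loops."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    adjacency = (np.abs(matrix.values) >= threshold).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    return BinaryNetwork(
        labels=list(matrix.labels), adjacency=adjacency, threshold=float(threshold)
    )


def clustering_coefficient(net: BinaryNetwork) -> float:
    """Mean over all nodes of the neighbor-pair connection fraction."""
    a = net.adjacency.astype(float)
    if a.shape[0] == 0:
        raise ValueError("empty node set")
    k = a.sum(axis=1)
    # diag(A^3)/2 counts edges among the neighbors of each node
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c_i = np.where(denom > 0, triangles / denom, 0.0)
    return float(np.mean(c_i))


def _geodesics(net: BinaryNetwork) -> np.ndarray:
    return shortest_path(csr_array(net.adjacency), method="D", unweighted=True)


def average_path_length(net: BinaryNetwork) -> float:
    """Mean geodesic distance over all reachable unordered node pairs."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("average path length needs at least 2 nodes")
    if net.n_edges == 0:
        raise ValueError("graph has no edges: no finite paths exist")
    d = _geodesics(net)[np.triu_indices(n, k=1)]
    return float(d[np.isfinite(d)].mean())


def is_connected(net: BinaryNetwork) -> bool:
    if net.n_nodes < 2:
        return True
    d = _geodesics(net)[np.triu_indices(net.n_nodes, k=1)]
    return bool(np.isfinite(d).all())


def average_degree(net: BinaryNetwork) -> float:
    """Mean node degree, 2E/N."""
    if net.n_nodes == 0:
        raise ValueError("empty node set")
    return float(net.adjacency.sum() / net.n_nodes)


@dataclass
class NetworkMetrics:
    """Indices of one binary network, optionally with null-model context.

    ``sigma`` is the small-worldness (C/C_rand)/(L/L_rand), present only when
    the null means are.  ``L`` is NaN for edgeless graphs.
    """

    C: float
    L: float
    K_mean: float
    threshold: float | None
    connected: bool
    n_unreachable_pairs: int = 0
    C_rand: float | None = None
    L_rand: float | None = None
    sigma: float | None = None


def network_metrics(net: BinaryNetwork) -> NetworkMetrics:
    """C, L, K_mean and connectivity status of one network."""
    n = net.n_nodes
    c = clustering_coefficient(net)
    k_mean = average_degree(net)
    if net.n_edges == 0:
        return NetworkMetrics(
            C=c, L=float("nan"), K_mean=k_mean, threshold=net.threshold,
            connected=False, n_unreachable_pairs=n * (n - 1) // 2,
        )
    d = _geodesics(net)[np.triu_indices(n, k=1)]
    finite = np.isfinite(d)
    return NetworkMetrics(
        C=c,
        L=float(d[finite].mean()),
        K_mean=k_mean,
        threshold=net.threshold,
        connected=bool(finite.all()),
        n_unreachable_pairs=int((~finite).sum()),
    )
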