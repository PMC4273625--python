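"""Nodal and global graph measures: global efficiency, eigenvector centrality,
and participation coefficients with hub-role classification.

Global efficiency of an n-node network with shortest path lengths d_ij is the
mean inverse distance over ordered node pairs,

    E = (1/n) Σ_i Σ_{j≠i} d_ij^{-1} / (n − 1),

with unreachable pairs contributing 0. The participation coefficient of node i
with degree k_i and κ_is edges into community s is

    P_i = 1 − Σ_s (κ_is / k_i)²,

0 when all edges stay inside one community and at most 1 − 1/N_M for N_M
communities (attained only by an even split).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .netbuild import AdjacencyMatrix
from .partition import Partition

__all__ = [
    "EfficiencyResult",
    "global_efficiency",
    "eigenvector_centrality",
    "participation_coefficient",
    "classify_role",
]

#: Role boundaries on the participation coefficient.
PROVINCIAL_MAX = 0.30
CONNECTOR_MAX = 0.75


@dataclass
class EfficiencyResult:
    value: float
    n: int


def global_efficiency(adjacency: AdjacencyMatrix | np.ndarray) -> EfficiencyResult:
    """Mean inverse shortest-path length over ordered node pairs (1/∞ = 0)."""
    a = adjacency.values if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    d = shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return EfficiencyResult(value=float(inv.sum() / (n * (n - 1))), n=n)


def eigenvector_centrality(
    matrix: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Dominant-eigenvector centrality of a nonnegative symmetric weight matrix.

    Computed by power iteration to ``tol``; the returned vector is nonnegative
    and normalized to unit maximum. Intended for the unthresholded consensus
    edge matrix, so centrality reflects edge consistency rather than a binary
    cutoff.
    """
    w = np.asarray(getattr(matrix, "values", matrix), float)
    if np.any(w < 0):
        raise ValueError("weight matrix must be nonnegative")
    if not np.any(w):
        raise ValueError("all-zero weight matrix")
    n = w.shape[0]
    # positive diagonal shift: same eigenvectors, but the Perron root becomes
    # strictly dominant so the iteration cannot oscillate on bipartite graphs
    shifted = w + w.max() * np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        nv = shifted @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            raise ValueError("power iteration collapsed to the zero vector")
        nv /= norm
        if np.abs(nv - v).max() < tol:
            v = nv
            break
        v = nv
    else:
        raise RuntimeError(f"eigenvector centrality did not converge in {max_iter} iterations")
    v = np.abs(v)
    return v / v.max()


def classify_role(p: float) -> str:
    """Hub role from the participation coefficient (provincial/connector/kinless)."""
    if p <= PROVINCIAL_MAX:
        return "provincial"
    if p <= CONNECTOR_MAX:
        return "connector"
    return "kinless"


def participation_coefficient(
    adjacency: AdjacencyMatrix | np.ndarray,
    partition: Partition | np.ndarray,
) -> tuple[np.ndarray, list[str]]:
    """Participation coefficient and role label per node.

    Isolated nodes get P = 0 (and the provincial label). With three
    communities P cannot exceed 2/3, so kinless hubs (P > 0.75) are impossible
    in a three-community network; the threshold is kept for generality.
    """
    a = adjacency.values if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency)
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    if len(labels) != a.shape[0]:
        raise ValueError("partition does not cover the graph's nodes")
    k = a.sum(axis=1).astype(float)
    comms = np.unique(labels)
    kappa = np.stack([a[:, labels == c].sum(axis=1) for c in comms], axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - ((kappa / k[:, None]) ** 2).sum(axis=1)
    p[k == 0] = 0.0
    roles = [classify_role(float(v)) for v in p]
    return p, roles
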