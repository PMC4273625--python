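"""Community structure: modularity, Louvain detection with restarts, consensus
assignment across subjects, and partition similarity via normalized mutual
information with randomized-network nulls.

Modularity of a partition M of an undirected graph is

    Q = Σ_{u∈M} [ e_uu − (Σ_v e_uv)² ],

where e_uv is the fraction of edge weight joining communities u and v (each
within-community edge contributing wholly to e_uu, so that Σ_v e_uv equals the
community's share of total degree).

NMI between two labelings of the same node set follows Kuncheva and
Hadjitodorov: with confusion counts N_ij, marginals N_i, N_j and N nodes,

    NMI = −2 Σ_ij N_ij ln(N_ij N / N_i N_j) / (Σ_i N_i ln(N_i/N) + Σ_j N_j ln(N_j/N)),

1 for identical assignments, 0 for independent ones (natural log; the base
cancels in the ratio).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np

from .netbuild import AdjacencyMatrix, ConsistencyMatrix

__all__ = [
    "Partition",
    "NMIResult",
    "modularity",
    "louvain_partition",
    "consensus_assignment",
    "nmi",
    "nmi_significance",
]


@dataclass
class Partition:
    """Community labels per ROI (positional, 0-indexed nodes)."""

    labels: np.ndarray
    modularity_q: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class NMIResult:
    nmi: float
    p_value: float | None
    n_null: int
    null_distributions: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    p_values: dict[str, float] = field(default_factory=dict)


def _weighted_modularity(w: np.ndarray, labels: np.ndarray) -> float:
    w = np.asarray(w, float)
    total = w[np.triu_indices_from(w, k=1)].sum()
    if total <= 0:
        raise ValueError("graph has no (positive) edges; modularity undefined")
    q = 0.0
    strengths = w.sum(axis=1)
    for c in np.unique(labels):
        mask = labels == c
        within = w[np.ix_(mask, mask)][np.triu_indices(mask.sum(), k=1)].sum()
        q += within / total - (strengths[mask].sum() / (2 * total)) ** 2
    return float(q)


def modularity(adjacency: AdjacencyMatrix | np.ndarray, partition: Partition | np.ndarray) -> float:
    """Newman modularity Q of a partition on an unweighted (or weighted) graph."""
    w = adjacency.values if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency, float)
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    if len(labels) != w.shape[0]:
        raise ValueError("partition does not cover the graph's nodes")
    return _weighted_modularity(w, labels)


def _louvain_once(w: np.ndarray, order: np.ndarray, run_seed: int) -> np.ndarray:
    """One Louvain (multilevel) run under a permuted node order."""
    ig.set_random_number_generator(random.Random(run_seed))
    wp = w[np.ix_(order, order)]
    iu, ju = np.nonzero(np.triu(wp, k=1))
    g = ig.Graph(n=wp.shape[0], edges=list(zip(iu.tolist(), ju.tolist())))
    membership = g.community_multilevel(weights=wp[iu, ju].tolist()).membership
    labels = np.empty(w.shape[0], dtype=int)
    labels[order] = membership
    return labels


def louvain_partition(
    matrix: AdjacencyMatrix | ConsistencyMatrix | np.ndarray,
    n_restarts: int = 100,
    seed: int | np.random.Generator = 0,
) -> Partition:
    """Louvain community detection, best of ``n_restarts`` seeded runs.

    Accepts a binary adjacency or any symmetric nonnegative weight matrix
    (e.g. a consensus assignment matrix). Each restart runs the multilevel
    heuristic under a different random node order; the partition with the
    highest (weighted) modularity is returned. Deterministic given the seed.
    """
    if isinstance(matrix, (AdjacencyMatrix, ConsistencyMatrix)):
        w = np.asarray(matrix.values, float)
    else:
        w = np.asarray(matrix, float)
    if np.any(w < 0):
        raise ValueError("weight matrix must be nonnegative")
    if not np.any(w[np.triu_indices_from(w, k=1)] > 0):
        raise ValueError("all-zero matrix: no communities to detect")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = w.shape[0]
    best_labels, best_q = None, -np.inf
    for r in range(max(1, n_restarts)):
        order = np.arange(n) if r == 0 else rng.permutation(n)
        labels = _louvain_once(w, order, int(rng.integers(0, 2**31 - 1)))
        q = _weighted_modularity(w, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return Partition(labels=best_labels, modularity_q=best_q)


def consensus_assignment(
    partitions: list[Partition],
    n_restarts: int = 100,
    seed: int | np.random.Generator = 0,
) -> tuple[ConsistencyMatrix, Partition]:
    """Consistent assignment matrix Ca and the group partition detected on it.

    Ca_ij is the fraction of subjects assigning ROIs i and j to one community;
    the group partition is the Louvain partition of Ca.
    """
    if not partitions:
        raise ValueError("need at least one subject partition")
    n = len(partitions[0])
    if any(len(p) != n for p in partitions):
        raise ValueError("subject partitions cover different ROI sets")
    ca = np.zeros((n, n))
    for p in partitions:
        ca += (p.labels[:, None] == p.labels[None, :]).astype(float)
    ca /= len(partitions)
    np.fill_diagonal(ca, 1.0)
    cam = ConsistencyMatrix(values=ca, kind="assignment")
    group = louvain_partition(ca * (1 - np.eye(n)), n_restarts=n_restarts, seed=seed)
    return cam, group


def nmi(p1: Partition | np.ndarray, p2: Partition | np.ndarray) -> float:
    """Normalized mutual information between two partitions of one node set.

    Degenerate cases: two single-community partitions are identical (1.0);
    if exactly one side is single-community it carries no information (0.0).
    """
    a = np.asarray(p1.labels if isinstance(p1, Partition) else p1)
    b = np.asarray(p2.labels if isinstance(p2, Partition) else p2)
    if len(a) != len(b):
        raise ValueError("partitions cover different node sets")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    c1, c2 = ai.max() + 1, bi.max() + 1
    if c1 == 1 and c2 == 1:
        return 1.0
    if c1 == 1 or c2 == 1:
        return 0.0
    nij = np.zeros((c1, c2))
    np.add.at(nij, (ai, bi), 1.0)
    # identical partitions (up to relabeling) have a permutation-like
    # confusion matrix; return exactly 1 rather than 1 +/- rounding error
    if c1 == c2 and ((nij > 0).sum(axis=0) == 1).all() and ((nij > 0).sum(axis=1) == 1).all():
        return 1.0
    ni, nj = nij.sum(axis=1), nij.sum(axis=0)
    nz = nij > 0
    num = (nij[nz] * np.log(nij[nz] * n / np.outer(ni, nj)[nz])).sum()
    den = (ni * np.log(ni / n)).sum() + (nj * np.log(nj / n)).sum()
    return float(min(max(-2 * num / den, 0.0), 1.0))


def _rewired_copy(a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    from .richclub import rewire_preserving_degree

    adj = rewire_preserving_degree(AdjacencyMatrix(values=a), seed=rng)
    return adj.values


def nmi_significance(
    ag: AdjacencyMatrix,
    reference: AdjacencyMatrix | Partition,
    n_null: int = 10_000,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 1,
) -> NMIResult:
    """Permutation significance of the NMI between two community structures.

    Against a second network: both networks are rewired degree-preservingly,
    communities are re-detected on each replicate pair and the null NMI
    recorded. Against an external reference partition (whose generating
    network is unknown): two nulls are built — degree-preserving rewirings of
    the network, and density-matched Erdős–Rényi graphs — their p-values are
    reported separately and the conservative (larger) one is returned.
    p uses the add-one estimator (1 + #{null ≥ observed}) / (1 + n_null).
    """
    if n_null < 100:
        raise ValueError("n_null must be at least 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    detect = lambda m: louvain_partition(m, n_restarts=n_restarts, seed=rng)  # noqa: E731
    p_obs = detect(ag.values)
    n = ag.n

    if isinstance(reference, AdjacencyMatrix):
        q_obs = detect(reference.values)
        observed = nmi(p_obs, q_obs)
        null = np.empty(n_null)
        for b in range(n_null):
            null[b] = nmi(detect(_rewired_copy(ag.values, rng)), detect(_rewired_copy(reference.values, rng)))
        p = (1 + int((null >= observed).sum())) / (1 + n_null)
        return NMIResult(observed, p, n_null, {"rewired": null}, {"rewired": p})

    observed = nmi(p_obs, reference)
    m = ag.n_edges
    null_rw = np.empty(n_null)
    null_er = np.empty(n_null)
    for b in range(n_null):
        null_rw[b] = nmi(detect(_rewired_copy(ag.values, rng)), reference)
        er = nx.gnm_random_graph(n, m, seed=int(rng.integers(0, 2**31 - 1)))
        null_er[b] = nmi(detect(nx.to_numpy_array(er)), reference)
    p_rw = (1 + int((null_rw >= observed).sum())) / (1 + n_null)
    p_er = (1 + int((null_er >= observed).sum())) / (1 + n_null)
    return NMIResult(
        observed,
        max(p_rw, p_er),
        n_null,
        {"rewired": null_rw, "random": null_er},
        {"rewired": p_rw, "random": p_er},
    )
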