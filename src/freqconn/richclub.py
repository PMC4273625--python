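"""Hub identification and rich-club analysis.

A hub is a node whose degree (in the thresholded group network) and
eigenvector centrality (in the unthresholded consensus edge matrix) both lie
at least one standard deviation above the network mean.

The rich-club k-density of the subgraph induced by nodes of degree strictly
greater than k, with N_k such nodes and E_k edges among them, is

    Φ(k) = 2 E_k / (N_k (N_k − 1)),

undefined when N_k < 2. Because Φ(k) rises with k even in random graphs, it is
compared per k against degree-preserving rewired null networks; the rich-club
regime is the (highest) contiguous k-range where Φ(k) falls in the upper
alpha tail of the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .metrics import eigenvector_centrality, participation_coefficient
from .netbuild import AdjacencyMatrix, ConsistencyMatrix
from .partition import Partition

__all__ = [
    "HubReport",
    "RichClubCurve",
    "detect_hubs",
    "rich_club_coefficient",
    "rewire_preserving_degree",
    "rich_club_regime",
]


@dataclass
class HubReport:
    """Hubs (1-based ROI ids) with the thresholds and per-hub rank/role detail."""

    hub_rois: list[int]
    degree_threshold: float
    centrality_threshold: float
    detail: dict[int, dict] = field(default_factory=dict)


@dataclass
class RichClubCurve:
    k_grid: np.ndarray
    phi: np.ndarray  # NaN where undefined
    phi_rand_mean: np.ndarray
    phi_normalized: np.ndarray
    null_quantile: np.ndarray
    regime: tuple[int, int] | None
    n_null: int
    alpha: float
    hub_match_k: int | None = None


def _dense_rank_desc(values: np.ndarray) -> np.ndarray:
    """Rank 1 = largest; equal values share a rank (as in published hub tables)."""
    uniq = np.unique(values)[::-1]
    return np.searchsorted(-uniq, -values) + 1


def detect_hubs(
    adjacency: AdjacencyMatrix,
    ce: ConsistencyMatrix | np.ndarray,
    partition: Partition | None = None,
) -> HubReport:
    """Nodes ≥ 1 SD above the mean in both degree and eigenvector centrality.

    SDs are population SDs over nodes. If a metric has zero spread across
    nodes it singles out no hub (a regular graph has no degree hubs). When a
    partition is supplied each hub also gets its participation coefficient and
    role.
    """
    deg = adjacency.degrees().astype(float)
    cent = eigenvector_centrality(ce.values if isinstance(ce, ConsistencyMatrix) else ce)
    if len(cent) != len(deg):
        raise ValueError("degree and centrality ROI sets differ")
    thr_d = deg.mean() + deg.std()
    thr_c = cent.mean() + cent.std()
    deg_ok = (deg >= thr_d) if deg.std() > 0 else np.zeros(len(deg), bool)
    cent_ok = (cent >= thr_c) if cent.std() > 0 else np.zeros(len(cent), bool)
    hubs = np.flatnonzero(deg_ok & cent_ok)
    detail: dict[int, dict] = {}
    if partition is not None:
        part, roles = participation_coefficient(adjacency, partition)
    deg_rank = _dense_rank_desc(deg)
    cent_rank = _dense_rank_desc(cent)
    for h in hubs:
        entry = {
            "degree": int(deg[h]),
            "degree_rank": int(deg_rank[h]),
            "centrality": float(cent[h]),
            "centrality_rank": int(cent_rank[h]),
        }
        if partition is not None:
            entry["participation"] = float(part[h])
            entry["role"] = roles[h]
        detail[int(h) + 1] = entry
    return HubReport(
        hub_rois=[int(h) + 1 for h in hubs],
        degree_threshold=float(thr_d),
        centrality_threshold=float(thr_c),
        detail=detail,
    )


def rich_club_coefficient(adjacency: AdjacencyMatrix | np.ndarray, k: int) -> float | None:
    """Φ(k) over nodes of degree strictly greater than k; None when N_k < 2."""
    a = adjacency.values if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency)
    deg = a.sum(axis=1)
    mask = deg > k
    nk = int(mask.sum())
    if nk < 2:
        return None
    ek = a[np.ix_(mask, mask)].sum() / 2
    return float(2 * ek / (nk * (nk - 1)))


def rewire_preserving_degree(
    adjacency: AdjacencyMatrix,
    n_swaps: int | None = None,
    seed: int | np.random.Generator = 0,
    max_tries: int | None = None,
) -> AdjacencyMatrix:
    """Randomize a network by double-edge swaps that preserve every degree.

    Each move picks two edges (a,b), (c,d) and rewires them to (a,d), (c,b),
    rejecting self-loops and duplicate edges. Defaults: 10·|E| attempted moves
    (``max_tries``) targeting ``n_swaps`` = |E| successful swaps. If the swap
    quota is unreachable within the attempt budget (e.g. a triangle admits no
    valid swap) a warning reports the partial randomization.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = adjacency.values
    edges = [tuple(e) for e in np.argwhere(np.triu(a, 1))]
    m = len(edges)
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    n_swaps = m if n_swaps is None else n_swaps
    max_tries = 10 * m if max_tries is None else max_tries
    edge_set = set(edges)
    done = tries = 0
    # draw attempt randomness in blocks to keep the rejection loop cheap
    while done < n_swaps and tries < max_tries:
        block = min(max_tries - tries, 1024)
        picks = rng.integers(0, m, size=(block, 2))
        flips = rng.random(block) < 0.5
        for (e1, e2), flip in zip(picks, flips):
            tries += 1
            if e1 == e2:
                continue
            a1, b1 = edges[e1]
            c1, d1 = edges[e2]
            if flip:
                c1, d1 = d1, c1
            # proposed: (a1, d1), (c1, b1)
            if len({a1, b1, c1, d1}) < 4:
                continue
            new1 = (min(a1, d1), max(a1, d1))
            new2 = (min(c1, b1), max(c1, b1))
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard(edges[e1])
            edge_set.discard(edges[e2])
            edge_set.add(new1)
            edge_set.add(new2)
            edges[e1], edges[e2] = new1, new2
            done += 1
            if done >= n_swaps:
                break
    if done < n_swaps:
        warnings.warn(
            f"degree-preserving rewiring: only {done}/{n_swaps} swaps succeeded "
            f"within {max_tries} attempts; returning partial randomization",
            stacklevel=2,
        )
    out = np.zeros_like(a)
    for i, j in edge_set:
        out[i, j] = out[j, i] = 1
    return AdjacencyMatrix(values=out, band=adjacency.band, sparsity=adjacency.sparsity)


def rich_club_regime(
    adjacency: AdjacencyMatrix,
    n_null: int = 1000,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
    hub_rois: list[int] | None = None,
) -> RichClubCurve:
    """Rich-club curve with a degree-preserving null and regime detection.

    Builds ``n_null`` rewired replicates, takes per-k the empirical
    ceil((1−alpha)·n_null)-th order statistic as the significance bar, and
    reports the maximal contiguous k-range where Φ(k) exceeds it (the highest
    such range if several). Φ_normalized = Φ / Φ_meanrand. When ``hub_rois``
    is given, records a k inside the regime at which the surviving subgraph is
    exactly the hub set, if one exists.
    """
    if n_null < 100:
        raise ValueError("n_null must be at least 100")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = adjacency.values
    deg = a.sum(axis=1).astype(int)
    kmax = int(deg.max())
    k_grid = np.arange(kmax)  # at k >= kmax no node survives
    masks = [deg > k for k in k_grid]

    def curve(mat: np.ndarray) -> np.ndarray:
        out = np.full(len(k_grid), np.nan)
        for idx, mask in enumerate(masks):
            nk = int(mask.sum())
            if nk >= 2:
                ek = mat[np.ix_(mask, mask)].sum() / 2
                out[idx] = 2 * ek / (nk * (nk - 1))
        return out

    phi = curve(a)
    null = np.empty((n_null, len(k_grid)))
    for b in range(n_null):
        null[b] = curve(rewire_preserving_degree(adjacency, seed=rng).values)
    counts = (~np.isnan(null)).sum(axis=0)
    phi_rand_mean = np.where(
        counts > 0, np.nansum(np.nan_to_num(null), axis=0) / np.maximum(counts, 1), np.nan
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_norm = phi / phi_rand_mean
    order = int(np.ceil((1 - alpha) * n_null))
    qtl = np.full(len(k_grid), np.nan)
    for idx in range(len(k_grid)):
        col = null[:, idx]
        col = col[~np.isnan(col)]
        if len(col):
            qtl[idx] = np.sort(col)[min(order, len(col)) - 1]

    sig = ~np.isnan(phi) & ~np.isnan(qtl) & (phi > qtl)
    regime = None
    start = None
    for idx, flag in enumerate(list(sig) + [False]):
        if flag and start is None:
            start = idx
        elif not flag and start is not None:
            regime = (int(k_grid[start]), int(k_grid[idx - 1]))  # keep last = highest range
            start = None

    hub_match_k = None
    if hub_rois is not None and regime is not None:
        hub_idx = set(r - 1 for r in hub_rois)
        for k in range(regime[0], regime[1] + 1):
            if set(np.flatnonzero(deg > k)) == hub_idx:
                hub_match_k = k
                break
    return RichClubCurve(
        k_grid=k_grid,
        phi=phi,
        phi_rand_mean=phi_rand_mean,
        phi_normalized=phi_norm,
        null_quantile=qtl,
        regime=regime,
        n_null=n_null,
        alpha=alpha,
        hub_match_k=hub_match_k,
    )
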