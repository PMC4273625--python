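"""Binary network construction: sparsity thresholding, surrogate coherence
nulls for the admissible-threshold floor, and group-level consistency matrices.

Sparsity S is the fraction of realized edges out of all n(n−1)/2 node pairs.
Thresholding at S keeps the floor(S·n(n−1)/2) strongest coherence pairs, so a
network's realized edge count is exact by construction and density-matched
across bands and subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .io import TimeSeriesPanel
from .spectra import Band, CoherenceMatrix, SpectralSettings, band_average, coherence_spectrum

__all__ = [
    "AdjacencyMatrix",
    "ConsistencyMatrix",
    "sparsity_threshold",
    "coherence_null",
    "validate_sparsity_floor",
    "consistency_matrix",
    "group_network",
]


@dataclass
class AdjacencyMatrix:
    """Symmetric binary ROI × ROI network with zero diagonal."""

    values: np.ndarray
    band: Band | None = None
    sparsity: float | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.values, 1).sum())

    def degrees(self) -> np.ndarray:
        return self.values.sum(axis=1).astype(int)

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(csr_matrix(self.values), directed=False)
        return n_comp == 1


@dataclass
class ConsistencyMatrix:
    """Across-subject consensus matrix in [0,1].

    ``kind='edge'`` (Ce): fraction of subjects exhibiting each edge.
    ``kind='assignment'`` (Ca): fraction of subjects co-assigning each ROI pair.
    """

    values: np.ndarray
    kind: str = "edge"
    band: Band | None = None


def _ranked_pairs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs sorted by descending value, ties by ascending (i, j)."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    # lexsort: last key is primary; (i, j) ascending breaks ties deterministically
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def edge_count_for_sparsity(n: int, s: float) -> int:
    return int(np.floor(s * n * (n - 1) / 2))


def sparsity_threshold(matrix: CoherenceMatrix | np.ndarray, s: float, band: Band | None = None) -> AdjacencyMatrix:
    """Binarize a symmetric weight matrix at sparsity ``s``.

    Keeps the ``floor(s·n(n−1)/2)`` strongest off-diagonal pairs; ties at the
    cutoff are broken by ascending (i, j) index so thresholding is
    deterministic and nested across thresholds.
    """
    if isinstance(matrix, CoherenceMatrix):
        band = band or matrix.band
        values = matrix.values
    else:
        values = np.asarray(matrix, float)
    if not 0 < s <= 1:
        raise ValueError(f"sparsity must lie in (0, 1], got {s}")
    n = values.shape[0]
    m = edge_count_for_sparsity(n, s)
    if m == 0:
        raise ValueError(f"sparsity threshold S={s} retains no edges for n={n}")
    ii, jj = _ranked_pairs(values)
    a = np.zeros((n, n), dtype=int)
    a[ii[:m], jj[:m]] = 1
    a |= a.T
    return AdjacencyMatrix(values=a, band=band, sparsity=s)


def _band_coherence_pair(x: np.ndarray, y: np.ndarray, dt: float, band: Band, settings: SpectralSettings) -> float:
    panel = TimeSeriesPanel(values=np.column_stack([x, y]), dt=dt, subject_id="pair")
    spec = coherence_spectrum(panel, settings)
    return float(band_average(spec, band).values[0, 1])


def coherence_null(
    panel: TimeSeriesPanel,
    pair: tuple[int, int],
    band: Band,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    settings: SpectralSettings | None = None,
    surrogate: str = "phase",
) -> tuple[np.ndarray, float]:
    """Surrogate null distribution of band-averaged coherence for one ROI pair.

    ``pair`` uses 1-based ROI ids. Each replicate destroys the temporal
    alignment of the pair while keeping each signal's autocorrelation:
    ``surrogate='phase'`` (default) regenerates one signal with its Fourier
    magnitudes and fresh random phases; ``'shift'`` circularly rotates it by
    a random offset of at least one Welch segment. Phase randomization is the
    default because the circular shift explores only ~n/step distinct segment
    alignments, which narrows the conditional null and inflates its false
    positive rate. Returns the empirical distribution and the critical value
    at the ceil((1−alpha)(n_boot+1))-th order statistic (exact exchangeable
    coverage).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if surrogate not in ("shift", "phase"):
        raise ValueError(f"unknown surrogate method {surrogate!r}")
    settings = settings or SpectralSettings()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    i, j = pair[0] - 1, pair[1] - 1
    x, y = panel.values[:, i], panel.values[:, j]
    if x.std() == 0 or y.std() == 0:
        raise ValueError(f"constant signal in pair {pair}")
    n = len(y)
    nperseg, noverlap = settings.nperseg, settings.noverlap
    step = nperseg - noverlap
    n_seg = (n - nperseg) // step + 1
    if n_seg < 2:
        raise ValueError("panel too short for the spectral settings")
    seg_idx = (np.arange(n_seg)[:, None] * step + np.arange(nperseg)[None, :])
    win = _sig.get_window(settings.window, nperseg)
    freqs = np.fft.rfftfreq(nperseg, d=panel.dt)
    bmask = (freqs >= band.lo - 1e-12) & (freqs < band.hi - 1e-12)
    if not bmask.any():
        raise ValueError(f"no frequency grid point falls in band [{band.lo}, {band.hi}] Hz")

    def seg_fft(sig2d: np.ndarray) -> np.ndarray:
        """(replicates, time) -> tapered, per-segment detrended rFFT in-band."""
        segs = sig2d[:, seg_idx]  # (rep, seg, nperseg)
        if settings.detrend:
            segs = _sig.detrend(segs, axis=-1, type=settings.detrend)
        return np.fft.rfft(segs * win, axis=-1)[..., bmask]

    fx = seg_fft(x[None, :])[0]  # (seg, bins)
    pxx = np.mean(np.abs(fx) ** 2, axis=0)
    null = np.empty(n_boot)
    chunk = 512
    for start in range(0, n_boot, chunk):
        size = min(chunk, n_boot - start)
        if surrogate == "shift":
            offs = rng.integers(nperseg, n - nperseg + 1, size=size)
            ys = y[(np.arange(n)[None, :] + offs[:, None]) % n]
        else:
            spec = np.fft.rfft(y)
            phases = np.exp(2j * np.pi * rng.random((size, len(spec))))
            phases[:, 0] = 1.0
            if n % 2 == 0:
                phases[:, -1] = 1.0
            ys = np.fft.irfft(spec[None, :] * phases, n=n, axis=-1)
        fy = seg_fft(ys)  # (rep, seg, bins)
        pxy = np.mean(np.conj(fx)[None] * fy, axis=1)
        pyy = np.mean(np.abs(fy) ** 2, axis=1)
        coh = np.abs(pxy) ** 2 / (pxx[None, :] * pyy)
        null[start : start + size] = coh.mean(axis=1)
    order = min(int(np.ceil((1 - alpha) * (n_boot + 1))), n_boot)
    return null, float(np.sort(null)[order - 1])


def pooled_coherence_null(
    panels: list[TimeSeriesPanel],
    band: Band,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    settings: SpectralSettings | None = None,
    surrogate: str = "phase",
) -> tuple[np.ndarray, float]:
    """Pooled surrogate null over randomly drawn (subject, ROI pair) combinations.

    Cheaper alternative to per-pair nulls: each replicate picks a subject and
    an ROI pair at random and computes one surrogate band coherence.
    """
    settings = settings or SpectralSettings()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_rois = panels[0].n_rois
    null = np.empty(n_boot)
    for b in range(n_boot):
        panel = panels[int(rng.integers(len(panels)))]
        i, j = rng.choice(n_rois, size=2, replace=False)
        x, y = panel.values[:, i], panel.values[:, j]
        if surrogate == "shift":
            off = int(rng.integers(settings.nperseg, panel.n_timepoints - settings.nperseg + 1))
            y = np.roll(y, off)
        else:
            spec = np.fft.rfft(y)
            ph = np.exp(2j * np.pi * rng.random(len(spec)))
            ph[0] = 1.0
            y = np.fft.irfft(spec * ph, n=len(y))
        null[b] = _band_coherence_pair(x, y, panel.dt, band, settings)
    order = min(int(np.ceil((1 - alpha) * (n_boot + 1))), n_boot)
    return null, float(np.sort(null)[order - 1])


def validate_sparsity_floor(
    matrices: list[CoherenceMatrix],
    s_grid: list[float],
    null_critical,
) -> tuple[float, dict[float, bool]]:
    """Largest sparsity in the grid whose implied coherence cutoff is significant.

    For each subject and each S, the cutoff is the weakest retained coherence
    (the m-th ranked value, m = floor(S·n(n−1)/2)). An S is admissible when the
    cutoff clears the null critical value for every subject. ``null_critical``
    is a scalar (pooled null) or a ``{(i, j): critical}`` mapping with 1-based
    ids (per-pair nulls).
    """
    grid = sorted(s_grid)
    if not all(0 < s < 1 for s in grid) or len(set(grid)) != len(grid):
        raise ValueError("sparsity grid must be strictly increasing values in (0, 1)")
    flags: dict[float, bool] = {}
    diagnostics: dict[float, list[str]] = {}
    for s in grid:
        ok = True
        fails = []
        for si, cm in enumerate(matrices):
            n = cm.values.shape[0]
            m = edge_count_for_sparsity(n, s)
            ii, jj = _ranked_pairs(cm.values)
            ci, cj = int(ii[m - 1]), int(jj[m - 1])
            cutoff = cm.values[ci, cj]
            if np.isscalar(null_critical):
                crit = float(null_critical)
            else:
                crit = float(null_critical[(ci + 1, cj + 1)])
            if cutoff <= crit:
                ok = False
                fails.append(f"subject {si}: cutoff {cutoff:.4f} <= null critical {crit:.4f}")
        flags[s] = ok
        diagnostics[s] = fails
    admissible = [s for s, ok in flags.items() if ok]
    if not admissible:
        detail = "; ".join(f"S={s}: {d[0]}" for s, d in diagnostics.items() if d)
        raise ValueError(f"no sparsity threshold in the grid is significant ({detail})")
    return max(admissible), flags


def consistency_matrix(adjacencies: list[AdjacencyMatrix]) -> ConsistencyMatrix:
    """Consistent edge matrix Ce: entrywise mean of the subjects' binary networks."""
    if not adjacencies:
        raise ValueError("need at least one adjacency matrix")
    band = adjacencies[0].band
    shape = adjacencies[0].values.shape
    for a in adjacencies:
        if a.values.shape != shape:
            raise ValueError("adjacency matrices differ in size")
        if (a.band is None) != (band is None) or (a.band is not None and a.band != band):
            raise ValueError("adjacency matrices come from different bands")
    ce = np.mean([a.values for a in adjacencies], axis=0)
    return ConsistencyMatrix(values=ce, kind="edge", band=band)


def group_network(ce: ConsistencyMatrix, s: float) -> tuple[AdjacencyMatrix, bool]:
    """Group network A^g: threshold Ce at sparsity ``s``; report connectedness.

    Connectedness (single component under breadth-first search) is returned as
    a flag, not enforced; pipeline-level selection keeps the smallest grid S
    whose group networks are connected in every band.
    """
    ag = sparsity_threshold(ce.values, s, band=ce.band)
    return ag, ag.is_connected()
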