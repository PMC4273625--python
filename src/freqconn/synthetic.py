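"""Synthetic multi-subject ROI cohorts with planted band-specific structure.

Each subject's panel is a sum of band-limited latent processes plus white
noise. Per band the cohort encodes three planted communities, but how sharply
they are segregated is band-specific:

* community coupling (``alphas``): every ROI follows its community's latent
  with this weight; higher alpha means stronger, cleaner intra-community
  coherence in that band.
* community blending (``blending``): ROIs sit on a fixed gradient within
  their community; a fraction of their community coupling is rotated toward a
  neighbouring community's latent. Near 0 the three communities are discrete
  blocks; near 1 the structure is a graded ring in which boundaries blur, so
  detected partitions are weaker (lower modularity) even though the planted
  three-way labels are unchanged. The gradient is a fixed property of the ROI
  (the same in every subject), as anatomy is.
* hub wiring (``hub_rois``, ``betas``, ``hub_boost``): designated hub ROIs
  divert a fraction ``beta`` of their community-coupled power to another
  community's latent (hubs of one community alternate over the remaining
  communities as targets), at amplitude ``hub_boost``·alpha. They acquire
  strong cross-community coherence — connector hubs — without losing their
  anchoring.
* shared background (``gammas``): one band-limited latent common to all ROIs,
  lifting inter-community coherence inside the band (both the intra- and
  inter-system coherence curves peak in the planted bands).
* per-subject amplitude variability (``amp_jitter``): all couplings of a
  (subject, band) are scaled by a log-normal factor, emulating band-specific
  signal-power differences between subjects.
* regional band power (``weak_rois``, ``weak_gain``): a fixed set of ROIs
  couples more weakly in selected bands, emulating regional variation in
  band-limited signal power.

Latents are zero-phase (forward–backward Butterworth) band-pass filtered
white noise standardized to unit variance: stationary stochastic processes,
not sinusoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .io import TimeSeriesPanel
from .spectra import Band

__all__ = ["GeneratorConfig", "PlantedStructure", "generate_cohort", "planted_truth", "planted_bands"]


def _default_partition() -> tuple[int, ...]:
    return tuple([1] * 29 + [2] * 29 + [3] * 29)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic resting cohort.

    Defaults mirror the recorded cohort the pipeline targets: 28 subjects of
    610 samples at dt = 2 s over 87 ROIs, with coherence concentrated in the
    0.01–0.03 Hz and 0.07–0.09 Hz bands. The lower band carries discrete,
    strongly segregated communities integrated through boosted connector
    hubs; the upper band carries the same three communities as a graded ring
    (weaker segregation) with milder hubs.
    """

    n_rois: int = 87
    n_subjects: int = 28
    n_timepoints: int = 610
    dt: float = 2.0
    bands: tuple[tuple[float, float], ...] = ((0.01, 0.03), (0.07, 0.09))
    alphas: tuple[float, ...] = (0.32, 0.32)
    gammas: tuple[float, ...] = (0.18, 0.08)
    blending: tuple[float, ...] = (0.10, 0.90)
    betas: tuple[float, ...] = (0.20, 0.45)
    hub_boost: tuple[float, ...] = (1.4, 1.3)
    weak_rois: tuple[int, ...] = (3, 10, 17, 24, 32, 42, 47, 53, 61, 68, 75, 82)
    weak_gain: tuple[float, ...] = (1.0, 0.58)
    planted_partition: tuple[int, ...] = field(default_factory=_default_partition)
    hub_rois: tuple[int, ...] = (5, 15, 34, 44, 63, 73)  # 1-based, two per default community
    noise_sd: float = 1.0
    amp_jitter: float = 0.42
    seed: int = 0
    nirs_confounds: bool = False  # add 0.3 Hz and 1 Hz sinusoidal physiology

    def __post_init__(self) -> None:
        nyq = 1.0 / (2 * self.dt)
        for lo, hi in self.bands:
            if not 0 < lo < hi < nyq:
                raise ValueError(f"band [{lo}, {hi}] must lie strictly below Nyquist {nyq} Hz")
        if len(self.planted_partition) != self.n_rois:
            raise ValueError("planted_partition must label every ROI exactly once")
        nb = len(self.bands)
        for name in ("alphas", "gammas", "blending", "betas", "hub_boost", "weak_gain"):
            vals = getattr(self, name)
            if len(vals) != nb:
                raise ValueError(f"need one {name} entry per band")
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} must be nonnegative")
        if any(not 0 <= b <= 1 for b in self.blending) or any(not 0 <= b < 1 for b in self.betas):
            raise ValueError("blending must lie in [0,1] and betas in [0,1)")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        if any(not 1 <= r <= self.n_rois for r in self.hub_rois):
            raise ValueError("hub_rois must be 1-based ROI ids")
        if any(not 1 <= r <= self.n_rois for r in self.weak_rois):
            raise ValueError("weak_rois must be 1-based ROI ids")
        if set(self.weak_rois) & set(self.hub_rois):
            raise ValueError("weak_rois and hub_rois must not overlap")
        # at least two half-overlapping Welch segments must fit ...
        if self.n_timepoints < 192:
            raise ValueError(
                f"n_timepoints={self.n_timepoints} too short for spectral estimation "
                "(need at least 192 samples for two 128-sample segments)"
            )
        # ... and the narrowest band must hold >= 2 grid points of a segment
        # length the run supports (power of two, at least 128)
        nperseg = max(128, 2 ** int(np.floor(np.log2(self.n_timepoints / 4))))
        df = 1.0 / (nperseg * self.dt)
        narrow = min(hi - lo for lo, hi in self.bands)
        if narrow / df < 2:
            raise ValueError(
                f"n_timepoints={self.n_timepoints} too short to resolve a {narrow} Hz band "
                f"(grid spacing {df:.5f} Hz)"
            )

    @classmethod
    def nirs(cls, **overrides) -> "GeneratorConfig":
        """Optical-imaging preset: dt = 0.1 s with physiological confounds on."""
        defaults = dict(dt=0.1, n_timepoints=12_000, nirs_confounds=True)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class PlantedStructure:
    """Ground truth the cohort encodes, one entry per band."""

    partitions: tuple[tuple[int, ...], ...]
    hub_sets: tuple[tuple[int, ...], ...]
    coherence_order: tuple[int, ...]  # band indices, strongest community coupling first


def _bandpass_noise(rng: np.random.Generator, n: int, band: tuple[float, float], fs: float) -> np.ndarray:
    sos = _sig.butter(4, band, btype="bandpass", fs=fs, output="sos")
    # pad so filtfilt transients do not touch the retained window
    x = _sig.sosfiltfilt(sos, rng.standard_normal(n + 400))[200 : 200 + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _gradient(labels: np.ndarray) -> np.ndarray:
    """Fixed within-community position in [-1, 1], identical for all subjects."""
    u = np.empty(len(labels))
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        u[idx] = np.linspace(-1.0, 1.0, len(idx)) if len(idx) > 1 else 0.0
    return u


def generate_cohort(config: GeneratorConfig) -> list[TimeSeriesPanel]:
    """Generate one panel per subject; deterministic given ``config.seed``.

    Per-subject random streams are spawned from the master seed at fixed
    offsets, so subjects are mutually independent but individually
    reproducible.
    """
    fs = 1.0 / config.dt
    labels = np.asarray(config.planted_partition)
    communities = list(np.unique(labels))
    ring_next = {c: communities[(i + 1) % len(communities)] for i, c in enumerate(communities)}
    ring_prev = {c: communities[(i - 1) % len(communities)] for i, c in enumerate(communities)}
    u = _gradient(labels)
    hub_mask = np.zeros(config.n_rois, bool)
    hub_mask[[r - 1 for r in config.hub_rois]] = True
    weak_mask = np.zeros(config.n_rois, bool)
    if config.weak_rois:
        weak_mask[[r - 1 for r in config.weak_rois]] = True
    t = np.arange(config.n_timepoints) * config.dt
    panels = []
    for subj in range(config.n_subjects):
        rng = np.random.default_rng([config.seed, subj])
        x = np.zeros((config.n_timepoints, config.n_rois))
        for b, band in enumerate(config.bands):
            latents = {c: _bandpass_noise(rng, config.n_timepoints, band, fs) for c in communities}
            shared = _bandpass_noise(rng, config.n_timepoints, band, fs)
            scale = float(np.exp(rng.normal(0.0, config.amp_jitter))) if config.amp_jitter else 1.0
            alpha = scale * config.alphas[b]
            gamma = scale * config.gammas[b]
            psi = config.blending[b] * (np.pi / 2) * u
            gain = np.where(weak_mask, config.weak_gain[b], 1.0)
            for c in communities:
                m = (labels == c) & ~hub_mask
                if m.any():
                    comm = (
                        np.cos(np.abs(psi[m]))[None, :] * latents[c][:, None]
                        + np.sin(np.clip(psi[m], 0, None))[None, :] * latents[ring_next[c]][:, None]
                        + np.sin(np.clip(-psi[m], 0, None))[None, :] * latents[ring_prev[c]][:, None]
                    )
                    x[:, m] += alpha * gain[None, m] * comm
                hub_idx = np.flatnonzero((labels == c) & hub_mask)
                if len(hub_idx):
                    beta = config.betas[b]
                    # alternate hub targets over the other communities so each
                    # hub bridges one partner community at full strength
                    others = [o for o in communities if o != c]
                    for pos, hi_ in enumerate(hub_idx):
                        target = latents[others[pos % len(others)]] if others else latents[c]
                        hub_sig = config.hub_boost[b] * alpha * (
                            np.sqrt(1 - beta) * latents[c] + np.sqrt(beta) * target
                        )
                        x[:, hi_] += hub_sig
            x += gamma * gain[None, :] * shared[:, None]
        x += config.noise_sd * rng.standard_normal(x.shape)
        if config.nirs_confounds:
            phase = rng.random(2) * 2 * np.pi
            x += 0.5 * np.sin(2 * np.pi * 0.3 * t + phase[0])[:, None]
            x += 0.5 * np.sin(2 * np.pi * 1.0 * t + phase[1])[:, None]
        panels.append(TimeSeriesPanel(values=x, dt=config.dt, subject_id=f"sim{subj:02d}"))
    return panels


def planted_truth(config: GeneratorConfig) -> PlantedStructure:
    """Ground-truth labels, per-band hub sets, and the expected coupling ordering.

    The planted three-way partition is the same in every band; what differs
    is how sharply it is expressed. Bands are ordered by decreasing effective
    community coupling alpha·(1 − blending/2).
    """
    hubs_per_band = tuple(
        tuple(sorted(config.hub_rois)) if config.betas[b] > 0 else ()
        for b in range(len(config.bands))
    )
    sharpness = [config.alphas[b] * (1 - config.blending[b] / 2) for b in range(len(config.bands))]
    order = tuple(int(i) for i in np.argsort(sharpness)[::-1])
    return PlantedStructure(
        partitions=tuple(tuple(config.planted_partition) for _ in config.bands),
        hub_sets=hubs_per_band,
        coherence_order=order,
    )


def planted_bands(config: GeneratorConfig) -> list[Band]:
    return [Band(lo, hi) for lo, hi in config.bands]
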