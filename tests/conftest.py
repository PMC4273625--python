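import numpy as np
import pytest

import freqconn as fc
from freqconn.synthetic import planted_bands


@pytest.fixture(scope="session")
def roi_table():
    return fc.load_roi_table()


@pytest.fixture(scope="session")
def small_cohort():
    """Six synthetic subjects at the default study conditions (fixed seed)."""
    cfg = fc.GeneratorConfig(n_subjects=6, seed=11)
    return cfg, fc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_spectra(small_cohort):
    cfg, panels = small_cohort
    return cfg, panels, [fc.coherence_spectrum(p) for p in panels]


@pytest.fixture(scope="session")
def vlf_band():
    return fc.Band(0.01, 0.03)


@pytest.fixture(scope="session")
def lf_band():
    return fc.Band(0.07, 0.09)


def two_cliques(k: int) -> np.ndarray:
    """Two disjoint k-cliques."""
    a = np.zeros((2 * k, 2 * k), dtype=int)
    a[:k, :k] = 1
    a[k:, k:] = 1
    np.fill_diagonal(a, 0)
    return a


def er_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T
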