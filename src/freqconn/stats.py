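"""Band-wise statistical comparison of subject-level graph metrics.

Each subject contributes one value per (metric, sparsity threshold) cell in
each of two frequency bands; cells are compared with a paired two-tailed
t-test and the whole grid of comparisons is corrected jointly with the
Benjamini–Yekutieli step-up FDR procedure, which is valid under arbitrary
dependence between the cells (they share subjects and nested edge sets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = ["TTestResult", "ComparisonReport", "paired_ttest", "fdr_by", "compare_bands"]


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


@dataclass
class ComparisonReport:
    """Per-cell comparison table plus the FDR family size and level."""

    table: pd.DataFrame
    m: int
    q: float
    bands: tuple[str, str]


def paired_ttest(x, y) -> TTestResult:
    """Two-tailed paired t-test on per-subject values from two conditions.

    One-sample t on the paired differences with n−1 degrees of freedom.
    Zero-variance differences are degenerate: flagged, p reported as 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D samples of at least 3 subjects")
    d = x - y
    sd = d.std(ddof=1)
    n = len(d)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else np.sign(d.mean()) * np.inf
        return TTestResult(t=float(t), p=1.0, df=n - 1, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * _st.t.sf(abs(t), df=n - 1)
    return TTestResult(t=float(t), p=float(p), df=n - 1)


def fdr_by(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Yekutieli step-up significance flags at FDR level ``q``.

    Sorted p-values p_(i) are compared against i·q/(m·c(m)) with the harmonic
    correction c(m) = Σ_{i=1..m} 1/i; all hypotheses up to the largest passing
    rank are flagged.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_by")
    return reject


def compare_bands(metrics: pd.DataFrame, q: float = 0.05) -> ComparisonReport:
    """Compare two bands over the full (metric × sparsity) grid of a cohort.

    ``metrics`` is long-form with columns ``subject``, ``band``, ``metric``,
    ``sparsity``, ``value``; exactly two bands must be present and every
    subject must fill every cell in both. With the default grid of five
    sparsity levels and two metrics (modularity Q, global efficiency E) the
    corrected family has m = 10 comparisons.
    """
    required = {"subject", "band", "metric", "sparsity", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics frame must have columns {sorted(required)}")
    bands = sorted(metrics["band"].unique())
    if len(bands) != 2:
        raise ValueError(f"exactly two bands required, found {bands}")
    cells = sorted(
        {(m, s) for m, s in zip(metrics["metric"], metrics["sparsity"])},
        key=lambda c: (c[0], c[1]),
    )
    subjects = sorted(metrics["subject"].unique())
    wide = metrics.set_index(["metric", "sparsity", "band", "subject"])["value"].sort_index()
    missing = [
        (mt, s, b, subj)
        for mt, s in cells
        for b in bands
        for subj in subjects
        if (mt, s, b, subj) not in wide.index
    ]
    if missing:
        raise ValueError(f"missing metric cells: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    rows = []
    for mt, s in cells:
        x = wide.loc[(mt, s, bands[0])].reindex(subjects).to_numpy()
        y = wide.loc[(mt, s, bands[1])].reindex(subjects).to_numpy()
        res = paired_ttest(x, y)
        rows.append(
            {
                "metric": mt,
                "sparsity": s,
                f"mean_{bands[0]}": x.mean(),
                f"mean_{bands[1]}": y.mean(),
                "t": res.t,
                "p": res.p,
                "degenerate": res.degenerate,
            }
        )
    table = pd.DataFrame(rows)
    table["significant"] = fdr_by(table["p"].to_numpy(), q=q)
    return ComparisonReport(table=table, m=len(table), q=q, bands=(bands[0], bands[1]))
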