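"""Input/output: the packaged ROI table, ROI time-series panels, and result files.

All user-facing ROI identifiers are 1-based, matching the packaged parcellation
table; every array inside the package is 0-indexed and conversion happens only
at this boundary (``roi_id = array_index + 1``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesPanel",
    "load_roi_table",
    "read_timeseries_panel",
    "write_results",
    "write_matrix",
    "read_matrix",
    "write_edge_list",
    "read_edge_list",
    "write_json_report",
]

ROI_TABLE_COLUMNS = [
    "roi_id",
    "mni_x",
    "mni_y",
    "mni_z",
    "dosenbach_label",
    "system",
    "aal_name",
    "community_vlf",
    "community_lf",
]

_SYSTEMS = {"default", "fronto-parietal", "cingulo-opercular"}


@dataclass
class TimeSeriesPanel:
    """One subject's ROI signals: a time × ROI matrix sampled every ``dt`` seconds."""

    values: np.ndarray
    dt: float
    subject_id: str = ""
    roi_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("panel values must be a 2-D time × ROI matrix")
        if self.values.shape[1] < 2:
            raise ValueError("panel needs at least 2 ROI columns")
        if not np.isfinite(self.values).all():
            raise ValueError("panel contains missing or non-finite values")
        if not self.dt > 0:
            raise ValueError("sampling interval dt must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


def load_roi_table() -> pd.DataFrame:
    """Load the packaged 87-ROI parcellation table.

    Columns: ``roi_id`` (1..87), ``mni_x/y/z`` (mm, MNI space),
    ``dosenbach_label``, ``system`` (default / fronto-parietal /
    cingulo-opercular), ``aal_name``, and the two published community
    assignment columns ``community_vlf`` and ``community_lf``. Community
    numerals are arbitrary names, not magnitudes.
    """
    ref = resources.files("freqconn.data").joinpath("roi_table.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    if list(table.columns) != ROI_TABLE_COLUMNS:
        raise ValueError(f"ROI table columns corrupted: {list(table.columns)}")
    if len(table) != 87:
        raise ValueError(f"ROI table must have 87 rows, found {len(table)}")
    ids = table["roi_id"].to_numpy()
    if not np.array_equal(ids, np.arange(1, 88)):
        bad = int(np.flatnonzero(ids != np.arange(1, 88))[0]) + 1
        raise ValueError(f"ROI table ids not contiguous starting at row {bad}")
    for row in table.itertuples():
        if row.system not in _SYSTEMS:
            raise ValueError(f"ROI table row {row.roi_id}: unknown system {row.system!r}")
        if row.community_vlf < 1 or row.community_lf < 1:
            raise ValueError(f"ROI table row {row.roi_id}: bad community label")
    return table


def _detect_delimiter(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    # single column or unsupported delimiter; single-ROI panels are invalid anyway
    raise ValueError("could not detect delimiter: only tab and comma are supported")


def read_timeseries_panel(path: str | Path, dt: float, subject_id: str | None = None) -> TimeSeriesPanel:
    """Read a delimited numeric time × ROI matrix; a non-numeric first row is a header."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty panel file")
    sep = _detect_delimiter(lines[0])
    first = lines[0].split(sep)
    roi_names = None
    start = 0
    try:
        [float(v) for v in first]
    except ValueError:
        roi_names = [v.strip() for v in first]
        start = 1
    n_cols = len(first)
    rows = []
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        cells = ln.split(sep)
        if len(cells) != n_cols:
            raise ValueError(f"{path}: line {lineno}: expected {n_cols} columns, got {len(cells)}")
        try:
            rows.append([float(v) for v in cells])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise ValueError(f"{path}: no numeric rows")
    return TimeSeriesPanel(
        values=np.asarray(rows, float),
        dt=dt,
        subject_id=subject_id or path.stem,
        roi_names=roi_names,
    )


def write_matrix(values: np.ndarray, path: str | Path) -> None:
    """Write a real-valued matrix as TSV at full double precision."""
    np.savetxt(path, np.asarray(values, float), delimiter="\t", fmt="%.17g")


def read_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def write_edge_list(adjacency: np.ndarray, path: str | Path) -> None:
    """Write an undirected binary network as ``i<TAB>j`` lines, i<j, 1-based ids."""
    a = np.asarray(adjacency)
    ii, jj = np.nonzero(np.triu(a, k=1))
    with open(path, "w") as fh:
        for i, j in zip(ii, jj):
            fh.write(f"{i + 1}\t{j + 1}\n")


def read_edge_list(path: str | Path, n_rois: int) -> np.ndarray:
    a = np.zeros((n_rois, n_rois), dtype=int)
    with open(path) as fh:
        for ln in fh:
            if ln.strip():
                i, j = (int(v) for v in ln.split())
                a[i - 1, j - 1] = a[j - 1, i - 1] = 1
    return a


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102 - stdlib hook
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if hasattr(o, "__dataclass_fields__"):
            return {k: getattr(o, k) for k in o.__dataclass_fields__}
        return super().default(o)


def write_json_report(report, path: str | Path) -> None:
    """Write any pipeline product (partition, hub report, regime, comparison) as JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, cls=_ReportEncoder, indent=1)
        fh.write("\n")


def write_results(product, path: str | Path) -> None:
    """Write any declared pipeline product in its standard text format.

    Binary networks become edge lists (``i<TAB>j``, 1-based); real-valued
    matrices (coherence, Ce, Ca) become TSV; partitions, hub reports,
    rich-club curves and comparison reports become JSON.
    """
    kind = type(product).__name__
    if kind == "AdjacencyMatrix":
        write_edge_list(product.values, path)
    elif kind in {"ConsistencyMatrix", "CoherenceMatrix"}:
        write_matrix(product.values, path)
    elif kind == "ComparisonReport":
        write_json_report(
            {"m": product.m, "q": product.q, "bands": product.bands,
             "table": product.table.to_dict(orient="records")},
            path,
        )
    elif hasattr(product, "__dataclass_fields__") or isinstance(product, dict):
        write_json_report(product, path)
    else:
        raise TypeError(f"cannot serialize pipeline product of type {kind}")
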