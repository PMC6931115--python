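"""Reading point files, preprocessing, and result serialization.

Point files are delimited text (CSV/TSV/whitespace), one point per row,
numeric coordinates, optionally a trailing integer ground-truth label
column.  Label files are one integer per line in input order, outliers as
-1, so clustering output composes directly with ``evaluate`` and external
tools.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .geometry import PointSet

__all__ = [
    "read_points",
    "standardize",
    "write_labels",
    "read_labels",
    "write_run_report",
    "ScanGrid",
    "parse_scan_range",
    "scan_parameters",
]


def read_points(
    path, delimiter: str | None = None, has_labels: bool = False
) -> tuple[PointSet, np.ndarray | None]:
    """Parse a delimited point file.

    ``delimiter=None`` sniffs commas, tabs or whitespace.  Ragged rows and
    non-numeric cells raise :class:`ParseError` naming the offending line
    (1-based).
    """
    text = Path(path).read_text()
    rows = [
        (i + 1, line.strip())
        for i, line in enumerate(text.splitlines())
        if line.strip()
    ]
    if not rows:
        raise ParseError(f"{path}: empty file")
    sep = delimiter
    if sep is None:
        first = rows[0][1]
        sep = "," if "," in first else ("\t" if "\t" in first else None)
    parsed = []
    width = None
    for lineno, line in rows:
        cells = [c for c in (line.split(sep) if sep else line.split()) if c != ""]
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ParseError(
                f"{path}: line {lineno}: expected {width} fields, got {len(cells)}"
            )
        vals = pd.to_numeric(pd.Series(cells), errors="coerce")
        if vals.isna().any():
            col = int(vals.isna().idxmax())
            raise ParseError(
                f"{path}: line {lineno}, column {col + 1}: "
                f"non-numeric value {cells[col]!r}"
            )
        parsed.append(vals.to_numpy(dtype=float))
    data = np.vstack(parsed)
    labels = None
    if has_labels:
        if data.shape[1] < 2:
            raise ParseError(f"{path}: need at least one coordinate column "
                             "besides the label column")
        labels = data[:, -1].astype(np.int64)
        data = data[:, :-1]
    return PointSet(data), labels


def standardize(points: PointSet, mode: str = "zscore") -> PointSet:
    """Feature-wise preprocessing.

    ``zscore`` subtracts the mean and scales to unit (population) variance,
    centering every feature around zero; a constant feature is centered but
    left unscaled, with a warning.  ``minmax`` maps each feature to [0, 1].
    ``none`` returns the input unchanged.
    """
    if mode == "none":
        return points
    coords = points.coords.copy()
    if mode == "zscore":
        mean = coords.mean(axis=0)
        std = coords.std(axis=0)
        const = std == 0
        if const.any():
            warnings.warn(
                f"constant feature(s) {np.flatnonzero(const).tolist()} "
                "centered but not scaled"
            )
        std = np.where(const, 1.0, std)
        return PointSet((coords - mean) / std)
    if mode == "minmax":
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        rng = np.where(hi > lo, hi - lo, 1.0)
        return PointSet((coords - lo) / rng)
    raise ValueError(f"unknown preprocessing mode {mode!r}")


def write_labels(path, labels) -> None:
    Path(path).write_text("\n".join(str(int(x)) for x in labels) + "\n")


def read_labels(path) -> np.ndarray:
    lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    try:
        return np.array([int(l) for l in lines], dtype=np.int64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer label: {exc}") from exc


def write_run_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


@dataclass(frozen=True)
class ScanGrid:
    """Inclusive (start : step : stop) grids for the alpha/beta scan."""

    alpha: tuple[float, float, float] = (0.1, 0.1, 1.0)
    beta: tuple[float, float, float] = (0.1, 0.1, 1.0)

    def values(self, which: str) -> np.ndarray:
        start, step, stop = getattr(self, which)
        if step <= 0 or start > stop:
            raise ValueError(f"invalid grid for {which}: {getattr(self, which)}")
        count = int(round((stop - start) / step)) + 1
        vals = start + step * np.arange(count)
        vals = vals[vals <= stop + 1e-9]
        return np.round(vals, 10)


def parse_scan_range(text: str) -> tuple[float, float, float]:
    """Parse the ``(start:step:stop)`` range notation, e.g. ``(0.1:0.1:1)``."""
    inner = text.strip().strip("()")
    parts = inner.split(":")
    if len(parts) != 3:
        raise ValueError(f"scan range must be (start:step:stop), got {text!r}")
    start, step, stop = (float(p) for p in parts)
    return (start, step, stop)


def scan_parameters(
    points: PointSet,
    true_labels: np.ndarray,
    grid: ScanGrid | None = None,
    criterion: str = "ari",
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """Grid-search alpha and beta, scoring each run by an external criterion.

    Returns one row per (alpha, beta) with all external criteria, sorted by
    the chosen criterion descending then by (alpha, beta) ascending, so the
    first row is the argmax with a lexicographically-smallest tie-break.
    """
    from .core import CutParams, cutesc_p
    from .metrics import external_report

    grid = grid or ScanGrid()
    rows = []
    for a in grid.values("alpha"):
        for b in grid.values("beta"):
            params = CutParams(alpha=float(a), beta=float(b),
                               min_cluster_size=min_cluster_size)
            labeling = cutesc_p(points, params)
            rep = external_report(true_labels, labeling.labels)
            rep.update(alpha=float(a), beta=float(b), k=labeling.k)
            rows.append(rep)
    df = pd.DataFrame(rows)
    if criterion not in df.columns:
        raise ValueError(f"unknown criterion {criterion!r}")
    return df.sort_values(
        [criterion, "alpha", "beta"], ascending=[False, True, True]
    ).reset_index(drop=True)
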