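"""Plain-text input/output.

Time-series files are wide CSV: first column the sampling time in hours,
one column per cell (header row required), blank cells meaning missing
observations.  Result tables, label sidecars and config files are CSV /
YAML.  Floats are written with 9 significant digits.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import Dataset, TimeSeries

__all__ = ["read_timeseries_csv", "write_timeseries_csv", "write_results_table", "write_labels_csv", "read_labels_csv"]

FLOAT_FMT = "%.9g"


def read_timeseries_csv(path) -> Dataset:
    """Read a wide time-series CSV into a :class:`Dataset`.

    Missing (blank) entries are dropped per cell, so different cells may
    have different lengths.  Malformed input (duplicate headers,
    non-numeric entries, non-ascending times) raises a descriptive error
    with the offending line number.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), None)
    if not header or len(header) < 2:
        raise ValueError(f"{path}: need a header row with a time column and at least one cell")
    cell_ids = [h.strip() for h in header[1:]]
    dupes = sorted({c for c in cell_ids if cell_ids.count(c) > 1})
    if dupes:
        raise ValueError(f"{path}, line 1: duplicate cell headers {dupes}")

    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise ValueError(f"{path}: parse failure: {exc}") from exc
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise ValueError(f"{path}, line {line}: non-numeric entry {df[col][bad].iloc[0]!r} in column {col!r}")
        df[col] = coerced

    times = df.iloc[:, 0].to_numpy(dtype=float)
    if np.isnan(times).any():
        line = int(np.flatnonzero(np.isnan(times))[0]) + 2
        raise ValueError(f"{path}, line {line}: missing time value")
    if np.any(np.diff(times) <= 0):
        line = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 3
        raise ValueError(f"{path}, line {line}: times must be strictly ascending")

    cells = []
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=float)
        mask = ~np.isnan(vals)
        if mask.sum() == 0:
            continue
        cells.append(TimeSeries(times[mask], vals[mask], cell_id=str(col).strip()))
    return Dataset(cells=cells, provenance={"source": str(path)})


def write_timeseries_csv(dataset: Dataset, path) -> None:
    """Write a dataset back to wide CSV (cells aligned on the union grid)."""
    all_times = np.unique(np.concatenate([c.times for c in dataset.cells]))
    data = {"time": all_times}
    for c in dataset.cells:
        col = np.full(all_times.size, np.nan)
        idx = np.searchsorted(all_times, c.times)
        col[idx] = c.values
        data[c.cell_id] = col
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_results_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_labels_csv(dataset: Dataset, path) -> None:
    """Sidecar CSV with each cell's ground-truth regime and generator metadata."""
    import json

    rows = []
    for c in dataset.cells:
        rows.append({
            "cell_id": c.cell_id,
            "regime": (dataset.labels or {}).get(c.cell_id, ""),
            "generator": json.dumps({str(k): v for k, v in dataset.provenance.items()}),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels_csv(path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["cell_id"].astype(str), df["regime"].astype(str)))
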