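"""Time-series containers shared across the package.

Times are in hours everywhere in the public API; the stochastic
simulators work in minutes internally and convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["TimeSeries", "Dataset"]


@dataclass
class TimeSeries:
    """A single cell's sampled signal.

    Parameters
    ----------
    times : array-like
        Sampling times in hours, finite and strictly ascending.
    values : array-like
        Measured signal, same length as ``times``.
    cell_id : str
        Label used in result tables.
    sigma_n_sq : float or None
        Known measurement-noise variance (e.g. injected by a simulator or
        estimated from background regions).  ``None`` means unknown.
    """

    times: np.ndarray
    values: np.ndarray
    cell_id: str = "cell"
    sigma_n_sq: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.shape != self.values.shape:
            raise ValueError(
                f"times (n={self.times.size}) and values (n={self.values.size}) "
                "must have the same length"
            )
        if not np.all(np.isfinite(self.times)):
            raise ValueError("non-finite time point")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite value")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly ascending")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def median_dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def centred(self) -> "TimeSeries":
        """Return a copy with the sample mean subtracted."""
        return TimeSeries(
            self.times,
            self.values - self.values.mean(),
            cell_id=self.cell_id,
            sigma_n_sq=self.sigma_n_sq,
            meta=dict(self.meta),
        )

    def standardised(self) -> "TimeSeries":
        """Return a z-scored copy (zero mean, unit sample variance)."""
        sd = self.values.std()
        if sd == 0:
            raise ValueError(f"cell {self.cell_id!r}: constant series cannot be standardised")
        return TimeSeries(
            self.times,
            (self.values - self.values.mean()) / sd,
            cell_id=self.cell_id,
            sigma_n_sq=self.sigma_n_sq,
            meta=dict(self.meta),
        )


@dataclass
class Dataset:
    """A collection of cells with optional ground-truth labels."""

    cells: list[TimeSeries]
    labels: dict[str, str] | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate cell ids: {dupes}")

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)
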