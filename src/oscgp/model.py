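"""Model/Results front end for the oscillation screen.

``OscillationScreen`` is the user-facing entry point: build it from a
:class:`Dataset` or a wide DataFrame (time column plus one column per
cell), call :meth:`fit`, and inspect the returned
:class:`OscillationScreenResults` -- per-cell estimates, q-values, the
bootstrap null, a ``summary()`` table and basic plots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import PipelineConfig, PipelineResult, run_pipeline
from .timeseries import Dataset, TimeSeries

__all__ = ["OscillationScreen", "OscillationScreenResults"]


class OscillationScreen:
    """Screen a population of single-cell time series for oscillations.

    Parameters
    ----------
    data : Dataset
        The cells to analyse.
    expected_period : float, optional
        Expected oscillation period in hours; sets the detrending bound
        to a minimum trend lengthscale of 3x the period.
    alpha_se_upper_bound : float, optional
        Explicit detrending bound (1/h^2) instead of ``expected_period``.
    gamma : float
        FDR level at which cells are called oscillatory.
    n_synth : int
        Size of the parametric-bootstrap null.
    sigma_n_sq : float, optional
        Fixed measurement-noise variance; per-cell values attached to the
        series take over when omitted, and otherwise the noise is
        optimised freely.
    """

    def __init__(self, data: Dataset, *, expected_period: float | None = None,
                 alpha_se_upper_bound: float | None = None, gamma: float = 0.05,
                 n_synth: int = 2000, restarts: int = 5,
                 sigma_n_sq: float | None = None):
        self.data = data
        self._kwargs = dict(
            expected_period=expected_period,
            alpha_se_upper_bound=alpha_se_upper_bound,
            gamma=gamma, n_synth=n_synth, restarts=restarts,
            sigma_n_sq=sigma_n_sq,
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "OscillationScreen":
        """Build from a wide DataFrame: first column time (hours), one
        column per cell; NaNs are treated as missing points."""
        times = frame.iloc[:, 0].to_numpy(dtype=float)
        cells = []
        for col in frame.columns[1:]:
            vals = frame[col].to_numpy(dtype=float)
            mask = ~np.isnan(vals)
            cells.append(TimeSeries(times[mask], vals[mask], cell_id=str(col)))
        return cls(Dataset(cells=cells), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "OscillationScreen":
        from .io import read_timeseries_csv

        return cls(read_timeseries_csv(path), **kwargs)

    def fit(self, seed: int = 0) -> "OscillationScreenResults":
        config = PipelineConfig(seed=seed, **self._kwargs)
        return OscillationScreenResults(self, run_pipeline(self.data, config), config)


class OscillationScreenResults:
    """Fitted screen: per-cell table, null distribution, FDR summary."""

    def __init__(self, model: OscillationScreen, result: PipelineResult,
                 config: PipelineConfig):
        self.model = model
        self._result = result
        self.config = config

    @property
    def provenance(self) -> dict:
        """Machine-readable run provenance (config, seeds, versions)."""
        return dict(self._result.provenance)

    @property
    def cells(self) -> pd.DataFrame:
        """Per-cell results: LLR, period, Q-factor, q-value, pass flag."""
        return self._result.table

    @property
    def null(self):
        return self._result.null

    @property
    def pi0(self) -> float:
        return self._result.fdr.pi0

    @property
    def n_pass(self) -> int:
        return self._result.fdr.n_pass

    @property
    def q_values(self) -> np.ndarray:
        return self._result.fdr.q_values

    def summary(self) -> str:
        t = self.cells
        usable = t[t.usable]
        lines = [
            "Oscillation screen",
            "==================",
            f"cells analysed:        {len(t)}",
            f"usable fits:           {len(usable)}",
            f"estimated pi0:         {self.pi0:.3f}",
            f"FDR level gamma:       {self.config.gamma:g}",
            f"cells passing:         {self.n_pass}",
            f"bootstrap null size:   {self.null.m_prime}",
        ]
        passing = usable[usable.passes]
        if len(passing):
            lines.append(
                f"period of passing cells (h): median {passing.period_hours.median():.2f}"
                f", IQR [{passing.period_hours.quantile(0.25):.2f}, "
                f"{passing.period_hours.quantile(0.75):.2f}]"
            )
        lines.append("")
        cols = ["cell_id", "n_points", "llr_normalized", "period_hours",
                "q_factor", "q_value", "passes"]
        with pd.option_context("display.float_format", "{:.4g}".format):
            lines.append(t[cols].to_string(index=False))
        return "\n".join(lines)

    def plot_llr_distributions(self, ax=None):
        """Histogram of data LLRs against the bootstrap null."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        usable = self.cells[self.cells.usable]
        bins = np.histogram_bin_edges(
            np.concatenate([usable.llr_normalized, self.null.llrs]), bins=30)
        ax.hist(self.null.llrs, bins=bins, density=True, alpha=0.5,
                label="bootstrap null")
        ax.hist(usable.llr_normalized, bins=bins, density=True, alpha=0.5,
                label="data")
        ax.set_xlabel("LLR (per 100 points)")
        ax.set_ylabel("density")
        ax.legend()
        return ax

    def plot_cell(self, cell_id: str, ax=None):
        """Raw series, fitted trend and detrended residual for one cell."""
        import matplotlib.pyplot as plt

        cell = next(c for c in self._result.cells if c.cell_id == cell_id)
        ts = next(c for c in self.model.data.cells if c.cell_id == cell_id)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(ts.times, ts.values, "k.-", label="data", lw=0.8)
        ax.plot(ts.times, cell.detrend.trend, "g--", label="fitted trend")
        ax.plot(ts.times, cell.detrend.detrended.values, "b-", alpha=0.6,
                label="detrended")
        ax.set_xlabel("time (h)")
        ax.set_title(f"{cell_id}: LLR={cell.llr_normalized:.2f}, "
                     f"q={cell.q_value:.3f}")
        ax.legend()
        return ax
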