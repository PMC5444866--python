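"""Parametric-bootstrap null distribution, pi0 estimation and q-values.

Classical likelihood-ratio asymptotics (Wilks' theorem) do not apply to
the OU-vs-OUosc comparison because the null model sits on the boundary of
the alternative (beta = 0).  The null distribution of the LLR is instead
obtained by a parametric bootstrap: synthetic non-oscillatory cells are
sampled from each data cell's fitted trend + OU + noise model and pushed
through the *full* pipeline (detrend, then OU/OUosc fits), and their LLRs
form the empirical null.  Sampling from a fitted null model to calibrate
a test statistic is a Cox test.

The proportion of truly non-oscillatory cells, pi0, is estimated by
comparing the lower tail of the data LLR distribution with the null's
over a grid of cutoffs lambda, smoothing pi0(lambda) with a natural cubic
spline (3 degrees of freedom) and reading off the value at the smallest
lambda -- the region where oscillators are absent.  q-values then follow
the Storey-Tibshirani construction with the empirical null in place of
the uniform p-value distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classify import CellResult, classify_cell
from .detrend import DetrendConfig
from .gp import FitConfig, sample_gp
from .timeseries import TimeSeries

__all__ = [
    "NullDistribution",
    "FdrSummary",
    "generate_bootstrap_null",
    "estimate_pi0",
    "compute_q_values",
    "classify_at_fdr",
]

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """LLRs of synthetic non-oscillatory (trend + OU + noise) cells."""

    llrs: np.ndarray  # normalised LLRs, sorted ascending
    llrs_raw: np.ndarray  # matching unnormalised LLRs
    sources: list[str] = field(default_factory=list)  # source cell id per synthetic cell

    def __post_init__(self) -> None:
        self.llrs = np.sort(np.asarray(self.llrs, dtype=float))
        self.llrs_raw = np.asarray(self.llrs_raw, dtype=float)

    @property
    def m_prime(self) -> int:
        return self.llrs.size


@dataclass
class FdrSummary:
    pi0: float
    lambda_grid: np.ndarray
    pi0_lambda: np.ndarray
    q_values: np.ndarray
    gamma: float
    n_pass: int


def _allocation(n_synth: int, n_sources: int) -> list[int]:
    """Equal split of synthetic cells across source cells, remainder round-robin."""
    base, rem = divmod(n_synth, n_sources)
    return [base + (1 if i < rem else 0) for i in range(n_sources)]


def generate_bootstrap_null(
    cell_results: list[CellResult],
    detrend_config: DetrendConfig,
    fit_config: FitConfig | None = None,
    n_synth: int = 2000,
    seed: int = 0,
) -> NullDistribution:
    """Simulate the LLR distribution expected from non-oscillating cells.

    Each usable data cell contributes an equal share of the ``n_synth``
    synthetic cells.  A synthetic cell is a sum of a sample from the
    cell's fitted SE trend, a sample from its fitted OU model, and i.i.d.
    Gaussian noise at the cell's sigma_n^2, on the cell's own time grid;
    it is then detrended and classified exactly like a data cell.  A
    synthetic cell whose fits fail is resampled once, then dropped.
    """
    if fit_config is None:
        fit_config = FitConfig()
    usable = [c for c in cell_results if c.usable]
    if not usable:
        raise ValueError("no usable cell fits to bootstrap from")

    counts = _allocation(n_synth, len(usable))
    ss = np.random.SeedSequence(seed)
    llrs, llrs_raw, sources = [], [], []
    synth_idx = 0
    for cell, n_cell in zip(usable, counts):
        times = cell.detrend.detrended.times
        ou_params = cell.ou_fit.params
        sn2 = cell.ou_fit.noise.sigma_n_sq
        trend_fit = cell.detrend.trend_fit
        for _ in range(n_cell):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            for attempt in range(2):
                f = sample_gp(ou_params, times, 0.0, 1, rng)[0].values
                if trend_fit.converged:
                    f = f + sample_gp(trend_fit.params, times, 0.0, 1, rng)[0].values
                if sn2 > 0:
                    f = f + rng.normal(0.0, np.sqrt(sn2), times.size)
                ts = TimeSeries(times, f, cell_id=f"synth_{synth_idx}", sigma_n_sq=sn2)
                res = classify_cell(ts, detrend_config, fit_config)
                if res.usable:
                    llrs.append(res.llr_normalized)
                    llrs_raw.append(res.llr_raw)
                    sources.append(cell.cell_id)
                    break
                if attempt == 1:
                    logger.warning(
                        "synthetic cell from %s failed twice; dropped", cell.cell_id
                    )
            synth_idx += 1

    order = np.argsort(llrs)
    return NullDistribution(
        llrs=np.asarray(llrs)[order],
        llrs_raw=np.asarray(llrs_raw)[order],
        sources=[sources[i] for i in order],
    )


def _natural_spline_fit(x: np.ndarray, y: np.ndarray, df: int = 3) -> np.ndarray:
    """Least-squares natural cubic regression spline, returned as fitted values.

    Built on patsy's ``cr`` (natural cubic) basis with ``df`` columns plus
    an intercept, mirroring the usual smoothing-spline-with-3-df step of
    the q-value literature.
    """
    from patsy import dmatrix

    X = np.asarray(dmatrix("cr(x, df=df)", {"x": x, "df": df}))
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X @ coef


def estimate_pi0(
    data_llrs,
    null_llrs,
    n_lambda: int = 19,
    return_curve: bool = False,
):
    """Estimate the proportion of non-oscillatory cells.

    For a grid of cutoffs lambda spanning the pooled LLR range (fractions
    0.1, 0.15, ..., 1.0 of the range), compute

        pi0(lambda) = [#{data LLR < lambda}/m] / [#{null LLR < lambda}/m']

    drop grid points where the null count is zero, smooth with a natural
    cubic spline (3 df) and evaluate at the smallest lambda.  The result
    is clamped to [1/m, 1].
    """
    data = np.asarray(data_llrs, dtype=float)
    null = np.asarray(null_llrs, dtype=float)
    if data.size == 0 or null.size == 0:
        raise ValueError("both LLR lists must be non-empty")
    if n_lambda < 5:
        raise ValueError("need at least 5 lambda grid points")
    pooled_lo = min(data.min(), null.min())
    pooled_hi = max(data.max(), null.max())
    if pooled_hi <= pooled_lo:
        raise ValueError("degenerate lambda grid: all LLRs identical")
    fractions = np.linspace(0.1, 1.0, n_lambda)
    grid = pooled_lo + fractions * (pooled_hi - pooled_lo)

    m, mp = data.size, null.size
    n_data = np.searchsorted(np.sort(data), grid, side="left")
    n_null = np.searchsorted(np.sort(null), grid, side="left")
    keep = n_null > 0
    if keep.sum() < 2:
        raise ValueError("null LLR counts vanish over the lambda grid")
    grid, n_data, n_null = grid[keep], n_data[keep], n_null[keep]
    pi0_lambda = (n_data / m) / (n_null / mp)

    if grid.size >= 5:
        fitted = _natural_spline_fit(grid, pi0_lambda)
    else:
        fitted = pi0_lambda
    pi0 = float(fitted[0])  # smallest lambda
    pi0 = float(np.clip(pi0, 1.0 / m, 1.0))
    if return_curve:
        return pi0, grid, pi0_lambda
    return pi0


def compute_q_values(data_llrs, null: NullDistribution | np.ndarray, pi0: float) -> np.ndarray:
    """q-value per cell given the empirical null and pi0.

    The q-value of a cell is the smallest estimated FDR over all
    rejection regions {LLR >= c} that still contain the cell, i.e. over
    cutoffs c <= L:

        q(L) = min_{c <= L}  pi0 * [#{null >= c}/m'] / [#{data >= c}/m]

    with c ranging over the observed data LLRs (between data points the
    ratio is minimised at the next data point, so this loses nothing).
    The running minimum makes q exactly monotone non-increasing in the
    LLR; results are clamped to [0, 1].  Note the direction of the
    minimisation: a cutoff *above* a cell's LLR would exclude the cell
    from the rejection set, and minimising over those would let a single
    extreme cell (beyond every null draw) drag all q-values to zero.
    """
    data = np.asarray(data_llrs, dtype=float)
    null_llrs = null.llrs if isinstance(null, NullDistribution) else np.sort(np.asarray(null, dtype=float))
    if data.size == 0 or null_llrs.size == 0:
        raise ValueError("both LLR lists must be non-empty")
    if not 0 < pi0 <= 1:
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    m, mp = data.size, null_llrs.size

    order = np.argsort(data)
    sorted_data = data[order]
    # at threshold t = sorted_data[i]: #{data >= t} = m - i (ties: use first index)
    first_idx = np.searchsorted(sorted_data, sorted_data, side="left")
    n_data_ge = m - first_idx
    n_null_ge = mp - np.searchsorted(null_llrs, sorted_data, side="left")
    ratio = pi0 * (n_null_ge / mp) / (n_data_ge / m)
    # min over cutoffs c <= each cell's LLR: prefix minimum in ascending order
    q_sorted = np.minimum.accumulate(ratio)
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def classify_at_fdr(
    results: list[CellResult],
    q_values: np.ndarray,
    gamma: float,
) -> list[CellResult]:
    """Set each cell's q-value and pass flag (passes iff q < gamma)."""
    if not 0 < gamma < 1:
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    q_values = np.asarray(q_values, dtype=float)
    if len(results) != q_values.size:
        raise ValueError("one q-value per cell required")
    for cell, q in zip(results, q_values):
        cell.q_value = float(q)
        cell.passes = bool(q < gamma)
    return results
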