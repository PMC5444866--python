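"""Squared-exponential GP detrending.

Long-term trends (drifting baseline, bleaching, slow growth effects)
mask oscillations because the likelihood of both the oscillatory and the
aperiodic model is dominated by the trend.  The pipeline therefore uses a
two-stage procedure: first fit a smooth SE-kernel GP with a *bounded*
inverse-squared-lengthscale (so the trend cannot become flexible enough
to absorb the oscillation itself), subtract its posterior mean, then fit
the OU/OUosc models to the residual.

The default bound ties the minimum trend lengthscale to three times the
expected oscillation period: l = 3 * period, alpha_se <= 1/(2 l^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gp import FitConfig, FitResult, fit_result_from_params, optimize_hyperparameters, posterior_mean
from .kernels import NoiseLevel, SEParams, alpha_se_from_lengthscale
from .timeseries import TimeSeries

__all__ = ["DetrendConfig", "DetrendResult", "default_bound_from_expected_period", "fit_trend"]

logger = logging.getLogger(__name__)


def default_bound_from_expected_period(expected_period: float) -> float:
    """Upper bound on alpha_se from the expected period (hours).

    Sets the minimum trend lengthscale to 3x the expected period,
    the recommended compromise between removing real trends and leaving
    the oscillation intact.
    """
    if not expected_period > 0:
        raise ValueError(f"expected_period must be > 0, got {expected_period}")
    return alpha_se_from_lengthscale(3.0 * expected_period)


@dataclass
class DetrendConfig:
    """Detrending settings.

    Exactly one of ``alpha_se_upper_bound`` (explicit, 1/h^2) or
    ``expected_period`` (hours; the bound is derived as 3x the period)
    must determine the bound.  An explicit bound wins if both are given.
    """

    alpha_se_upper_bound: float | None = None
    expected_period: float | None = None

    def __post_init__(self) -> None:
        if self.alpha_se_upper_bound is None:
            if self.expected_period is None:
                raise ValueError("need alpha_se_upper_bound or expected_period")
            self.alpha_se_upper_bound = default_bound_from_expected_period(self.expected_period)
        if not self.alpha_se_upper_bound > 0:
            raise ValueError("alpha_se_upper_bound must be > 0")


@dataclass
class DetrendResult:
    trend_fit: FitResult
    trend: np.ndarray  # trend values at the data times (original units)
    detrended: TimeSeries  # original - trend
    fallback: bool = False  # True when the SE fit failed and only the mean was removed


def fit_trend(
    ts: TimeSeries,
    config: DetrendConfig,
    fit_config: FitConfig | None = None,
) -> DetrendResult:
    """Fit a bounded SE trend and subtract it.

    The SE model is fitted with a free noise term: everything that is not
    smooth on the allowed lengthscale (oscillations, OU fluctuations and
    measurement noise alike) is absorbed by that term, and only the smooth
    posterior mean is removed.  The fitted noise variance is deliberately
    not reused downstream.  If the optimisation fails entirely the series
    is mean-centred instead, with a warning.
    """
    if fit_config is None:
        fit_config = FitConfig()
    bound_log = float(np.log(config.alpha_se_upper_bound))
    # very tight bounds (huge lengthscales) push the whole box downward
    lower_log = min(-12.0, bound_log - 6.0)
    se_config = FitConfig(
        restarts=fit_config.restarts,
        seed=fit_config.seed,
        noise_mode="free",
        bounds={**fit_config.bounds, "alpha_se": (lower_log, bound_log)},
        maxiter=fit_config.maxiter,
    )
    mean = float(ts.values.mean())
    centred = TimeSeries(ts.times, ts.values - mean, cell_id=ts.cell_id,
                         sigma_n_sq=ts.sigma_n_sq)
    fit = optimize_hyperparameters(centred, "se", se_config)
    if not fit.converged:
        logger.warning(
            "cell %s: SE trend fit failed (%s); falling back to mean subtraction",
            ts.cell_id, fit.message,
        )
        trend = np.full(len(ts), mean)
        fallback_fit = fit_result_from_params(
            SEParams(alpha_se=config.alpha_se_upper_bound, sigma_se=1e-12),
            NoiseLevel(max(float(ts.values.var()), 1e-12)),
        )
        fallback_fit.converged = False
        detrended = TimeSeries(ts.times, ts.values - trend, cell_id=ts.cell_id,
                               sigma_n_sq=ts.sigma_n_sq, meta=dict(ts.meta))
        return DetrendResult(fallback_fit, trend, detrended, fallback=True)

    trend = mean + posterior_mean(centred, fit, ts.times)
    detrended = TimeSeries(ts.times, ts.values - trend, cell_id=ts.cell_id,
                           sigma_n_sq=ts.sigma_n_sq, meta=dict(ts.meta))
    return DetrendResult(fit, trend, detrended)
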