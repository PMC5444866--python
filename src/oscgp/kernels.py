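"""Stationary covariance functions for single-cell expression dynamics.

Three kernel families are used throughout the package:

* ``OU`` -- Ornstein-Uhlenbeck, K(tau) = sigma * exp(-alpha*tau).  A
  mean-reverting process with exponentially decaying correlations; the
  null model of aperiodic (but correlated) fluctuations.
* ``OUosc`` -- quasi-periodic, K(tau) = sigma * exp(-alpha*tau) * cos(beta*tau).
  A stochastic oscillator whose phase drifts on the timescale 1/alpha;
  ``beta`` is an angular frequency (radians/hour), so the oscillation
  period is 2*pi/beta.  At beta = 0 it collapses exactly to the OU kernel,
  which is the nesting the likelihood-ratio test relies on.
* ``SE`` -- squared exponential, K(tau) = sigma_se * exp(-alpha_se*tau**2),
  a smooth process used to model slow long-term trends.  ``alpha_se`` maps
  to a correlation lengthscale l = 1/sqrt(2*alpha_se).

All kernels are stationary: tau is the absolute time difference |t - t'|
in hours, and only non-negative lags are accepted.  ``sigma`` is the
signal variance, i.e. K(0) = sigma exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "OUParams",
    "OUoscParams",
    "SEParams",
    "NoiseLevel",
    "ou_covariance",
    "ouosc_covariance",
    "se_covariance",
    "lengthscale_from_alpha_se",
    "alpha_se_from_lengthscale",
    "q_factor",
    "build_covariance_matrix",
    "cholesky_with_jitter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck kernel: decay rate ``alpha`` (1/h), variance ``sigma``."""

    alpha: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class OUoscParams:
    """Quasi-periodic kernel: decay ``alpha`` (1/h), angular frequency
    ``beta`` (rad/h), variance ``sigma``."""

    alpha: float
    beta: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def period(self) -> float:
        """Oscillation period 2*pi/beta in hours (inf when beta = 0)."""
        return float(2.0 * np.pi / self.beta) if self.beta > 0 else np.inf


@dataclass(frozen=True)
class SEParams:
    """Squared-exponential trend kernel: inverse-squared-lengthscale
    ``alpha_se`` (1/h^2), variance ``sigma_se``."""

    alpha_se: float
    sigma_se: float

    def __post_init__(self) -> None:
        if not self.alpha_se > 0:
            raise ValueError(f"alpha_se must be > 0, got {self.alpha_se}")
        if not self.sigma_se > 0:
            raise ValueError(f"sigma_se must be > 0, got {self.sigma_se}")

    @property
    def lengthscale(self) -> float:
        return lengthscale_from_alpha_se(self.alpha_se)


@dataclass(frozen=True)
class NoiseLevel:
    """Measurement-noise variance sigma_n^2 (squared signal units)."""

    sigma_n_sq: float

    def __post_init__(self) -> None:
        if self.sigma_n_sq < 0:
            raise ValueError(f"sigma_n_sq must be >= 0, got {self.sigma_n_sq}")


def _check_tau(tau):
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lags are absolute time differences and must be >= 0")
    return tau


def ou_covariance(params: OUParams, tau):
    """Evaluate the OU kernel sigma * exp(-alpha*tau) at lag(s) ``tau``."""
    tau = _check_tau(tau)
    return params.sigma * np.exp(-params.alpha * tau)


def ouosc_covariance(params: OUoscParams, tau):
    """Evaluate the quasi-periodic kernel sigma * exp(-alpha*tau) * cos(beta*tau)."""
    tau = _check_tau(tau)
    return params.sigma * np.exp(-params.alpha * tau) * np.cos(params.beta * tau)


def se_covariance(params: SEParams, tau):
    """Evaluate the squared-exponential kernel sigma_se * exp(-alpha_se*tau^2)."""
    tau = _check_tau(tau)
    return params.sigma_se * np.exp(-params.alpha_se * tau**2)


def lengthscale_from_alpha_se(alpha_se: float) -> float:
    """Correlation lengthscale l = 1/sqrt(2*alpha_se) of the SE kernel, hours."""
    if not alpha_se > 0:
        raise ValueError(f"alpha_se must be > 0, got {alpha_se}")
    return float(1.0 / np.sqrt(2.0 * alpha_se))


def alpha_se_from_lengthscale(lengthscale: float) -> float:
    """Inverse of :func:`lengthscale_from_alpha_se`."""
    if not lengthscale > 0:
        raise ValueError(f"lengthscale must be > 0, got {lengthscale}")
    return float(1.0 / (2.0 * lengthscale**2))


def q_factor(params: OUoscParams) -> float:
    """Oscillation quality factor Q = beta / (2*pi*alpha).

    The ratio of the oscillation frequency to the damping rate: high Q
    means many coherent cycles before the phase drifts, Q = 0 means no
    oscillation at all.
    """
    return float(params.beta / (2.0 * np.pi * params.alpha))


def covariance(params, tau):
    """Dispatch on the parameter type (OU / OUosc / SE)."""
    if isinstance(params, OUParams):
        return ou_covariance(params, tau)
    if isinstance(params, OUoscParams):
        return ouosc_covariance(params, tau)
    if isinstance(params, SEParams):
        return se_covariance(params, tau)
    raise TypeError(f"unknown kernel parameters: {type(params).__name__}")


def build_covariance_matrix(params, times, noise: NoiseLevel | float = 0.0) -> np.ndarray:
    """Gram matrix K(|t_i - t_j|) + sigma_n^2 * I on the given time grid.

    ``times`` must be finite and ascending (uneven spacing is fine).
    Duplicate time points are rejected when the noise variance is zero,
    since the resulting matrix is exactly singular.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if not np.all(np.isfinite(times)):
        raise ValueError("non-finite time point")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be ascending")
    sigma_n_sq = noise.sigma_n_sq if isinstance(noise, NoiseLevel) else float(noise)
    dup = np.flatnonzero(np.diff(times) == 0)
    if dup.size and sigma_n_sq == 0:
        pairs = [(int(i), int(i + 1)) for i in dup]
        raise ValueError(
            f"duplicate time points at index pairs {pairs} make the "
            "noise-free covariance matrix singular"
        )
    tau = np.abs(times[:, None] - times[None, :])
    K = covariance(params, tau)
    if sigma_n_sq:
        K = K + sigma_n_sq * np.eye(times.size)
    return K


def cholesky_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower-triangular Cholesky factor of ``K``, adding diagonal jitter
    if needed.

    Starts at 1e-8 times the mean diagonal and escalates tenfold up to
    1e-4 before giving up; every escalation is logged.

    Returns
    -------
    (L, jitter) where ``jitter`` is the absolute value added to the
    diagonal (0.0 if none was needed).
    """
    try:
        return scipy.linalg.cholesky(K, lower=True), 0.0
    except scipy.linalg.LinAlgError:
        pass
    scale = float(np.mean(np.diag(K)))
    if scale <= 0:
        scale = 1.0
    rel = 1e-8
    eye = np.eye(K.shape[0])
    while rel <= 1e-4:
        jitter = rel * scale
        logger.warning("Cholesky failed; retrying with jitter %.1e", jitter)
        try:
            return scipy.linalg.cholesky(K + jitter * eye, lower=True), jitter
        except scipy.linalg.LinAlgError:
            rel *= 10.0
    raise np.linalg.LinAlgError(
        "covariance matrix not positive definite even after jitter up to "
        f"1e-4 * mean diagonal ({1e-4 * scale:.3e})"
    )
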