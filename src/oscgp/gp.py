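"""Exact Gaussian-process regression for the package's kernel families.

The model is a zero-mean GP observed through additive Gaussian noise:

    y ~ N(0, K_theta(t, t) + sigma_n^2 I)

The log marginal likelihood

    log p(y | t, theta) = -1/2 y^T Ky^-1 y - 1/2 log|Ky| - n/2 log(2 pi)

and its gradient with respect to the (log) hyperparameters

    d/dtheta_j log p = 1/2 y^T Ky^-1 (dKy/dtheta_j) Ky^-1 y
                       - 1/2 tr(Ky^-1 dKy/dtheta_j)

are computed via Cholesky factorisation (never an explicit inverse).
All hyperparameters are optimised in log-space to enforce positivity,
with box bounds and randomised multi-start L-BFGS-B, because the
marginal-likelihood surface of the quasi-periodic kernel is multimodal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.signal

from .kernels import (
    NoiseLevel,
    OUParams,
    OUoscParams,
    SEParams,
    build_covariance_matrix,
    cholesky_with_jitter,
)
from .timeseries import TimeSeries

__all__ = [
    "FitConfig",
    "FitResult",
    "log_marginal_likelihood",
    "lml_gradient",
    "optimize_hyperparameters",
    "posterior_mean",
    "sample_gp",
]

_LOG2PI = float(np.log(2.0 * np.pi))

# log-space parameter names per kernel family, in vector order
_FAMILY_PARAMS = {
    "ou": ("alpha", "sigma"),
    "ouosc": ("alpha", "beta", "sigma"),
    "se": ("alpha_se", "sigma_se"),
}


def params_to_vector(params) -> tuple[str, np.ndarray]:
    """Kernel dataclass -> (family tag, log-parameter vector)."""
    if isinstance(params, OUParams):
        return "ou", np.log([params.alpha, params.sigma])
    if isinstance(params, OUoscParams):
        beta = max(params.beta, 1e-300)  # log-space representation needs beta > 0
        return "ouosc", np.log([params.alpha, beta, params.sigma])
    if isinstance(params, SEParams):
        return "se", np.log([params.alpha_se, params.sigma_se])
    raise TypeError(f"unknown kernel parameters: {type(params).__name__}")


def vector_to_params(family: str, theta: np.ndarray):
    v = np.exp(theta)
    if family == "ou":
        return OUParams(alpha=v[0], sigma=v[1])
    if family == "ouosc":
        return OUoscParams(alpha=v[0], beta=v[1], sigma=v[2])
    if family == "se":
        return SEParams(alpha_se=v[0], sigma_se=v[1])
    raise ValueError(f"unknown kernel family {family!r}")


@dataclass
class FitConfig:
    """Settings for hyperparameter optimisation.

    ``restarts`` counts randomised initialisations (log-uniform within the
    bounds); a small set of data-informed starts is always added on top.
    ``noise_mode`` is ``"fixed"`` (sigma_n^2 supplied, e.g. known injected
    noise or a background estimate) or ``"free"`` (optimised with a lower
    bound of 1e-6 * var(y)).
    """

    restarts: int = 10
    seed: int = 0
    noise_mode: str = "fixed"  # "fixed" | "free"
    sigma_n_sq: float = 0.0
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    maxiter: int = 200

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.noise_mode not in ("fixed", "free"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite and ordered")


@dataclass
class FitResult:
    """Optimised hyperparameters for one kernel family on one series."""

    family: str
    params: object
    noise: NoiseLevel
    log_marginal_likelihood: float
    converged: bool
    n_restarts_used: int = 0
    message: str = ""

    @property
    def theta(self) -> np.ndarray:
        return params_to_vector(self.params)[1]


def _kernel_cov_and_grads(family: str, theta: np.ndarray, tau: np.ndarray):
    """Covariance matrix and its derivatives w.r.t. each log-parameter."""
    if family == "ou":
        alpha, sigma = np.exp(theta)
        K = sigma * np.exp(-alpha * tau)
        return K, (-alpha * tau * K, K)
    if family == "ouosc":
        alpha, beta, sigma = np.exp(theta)
        E = sigma * np.exp(-alpha * tau)
        K = E * np.cos(beta * tau)
        dK_dlogbeta = -beta * tau * E * np.sin(beta * tau)
        return K, (-alpha * tau * K, dK_dlogbeta, K)
    if family == "se":
        alpha_se, sigma_se = np.exp(theta)
        K = sigma_se * np.exp(-alpha_se * tau**2)
        return K, (-alpha_se * tau**2 * K, K)
    raise ValueError(f"unknown kernel family {family!r}")


def _chol_lower_jittered(Ky):
    """LAPACK Cholesky with the package's escalating-jitter policy."""
    from scipy.linalg.lapack import dpotrf

    # clean=1 zeroes the upper triangle, which the dpotri symmetrisation
    # downstream relies on
    L, info = dpotrf(Ky, lower=1, clean=1, overwrite_a=0)
    if info == 0:
        return L
    scale = float(np.mean(np.diag(Ky))) or 1.0
    rel = 1e-8
    eye = np.eye(Ky.shape[0])
    while rel <= 1e-4:
        import logging

        logging.getLogger("oscgp.kernels").warning(
            "Cholesky failed; retrying with jitter %.1e", rel * scale)
        L, info = dpotrf(Ky + rel * scale * eye, lower=1, clean=1, overwrite_a=0)
        if info == 0:
            return L
        rel *= 10.0
    raise np.linalg.LinAlgError("covariance matrix not positive definite after jitter")


def _lml_and_grad(y, tau, family, x, free_noise, sigma_n_sq):
    """Log marginal likelihood and gradient over the optimisation vector.

    ``x`` is the log-kernel-parameter vector, with log(sigma_n^2) appended
    when the noise is free.  Uses direct LAPACK calls (dpotrf/dpotrs/
    dpotri): this sits in the innermost loop of every fit.
    """
    from scipy.linalg.lapack import dpotri, dpotrs

    n = y.size
    if free_noise:
        theta, sn2 = x[:-1], float(np.exp(x[-1]))
    else:
        theta, sn2 = x, sigma_n_sq
    K, dKs = _kernel_cov_and_grads(family, theta, tau)
    Ky = K.copy()  # the derivative w.r.t. log sigma aliases K itself
    idx = np.arange(n)
    Ky[idx, idx] += sn2
    L = _chol_lower_jittered(Ky)
    a, _ = dpotrs(L, y, lower=1)
    lml = -0.5 * float(y @ a) - float(np.log(np.diag(L)).sum()) - 0.5 * n * _LOG2PI
    Kinv, _ = dpotri(L, lower=1)  # lower triangle of Ky^-1
    Kinv = Kinv + Kinv.T
    Kinv[idx, idx] *= 0.5
    M = np.outer(a, a) - Kinv
    grad = np.empty(len(dKs) + (1 if free_noise else 0))
    for j, dK in enumerate(dKs):
        grad[j] = 0.5 * float(np.sum(M * dK))
    if free_noise:
        grad[-1] = 0.5 * sn2 * float(np.trace(M))
    return lml, grad


def log_marginal_likelihood(ts: TimeSeries, params, noise: NoiseLevel | float = 0.0) -> float:
    """Evaluate log p(y | t, theta) for fixed kernel parameters."""
    sn2 = noise.sigma_n_sq if isinstance(noise, NoiseLevel) else float(noise)
    family, theta = params_to_vector(params)
    tau = np.abs(ts.times[:, None] - ts.times[None, :])
    lml, _ = _lml_and_grad(ts.values, tau, family, theta, False, sn2)
    return lml


def lml_gradient(ts: TimeSeries, params, noise: NoiseLevel | float = 0.0) -> np.ndarray:
    """Gradient of the log marginal likelihood over the log-kernel-parameters."""
    sn2 = noise.sigma_n_sq if isinstance(noise, NoiseLevel) else float(noise)
    family, theta = params_to_vector(params)
    tau = np.abs(ts.times[:, None] - ts.times[None, :])
    _, grad = _lml_and_grad(ts.values, tau, family, theta, False, sn2)
    return grad


def default_bounds(family: str, ts: TimeSeries) -> dict[str, tuple[float, float]]:
    """Log-space box bounds per hyperparameter.

    The frequency bound keeps the fitted period inside
    [2 * median sampling interval, 2 * series duration], which prevents
    both aliasing beyond the sampling rate and "oscillations" slower than
    the record itself (those belong to the trend model).
    """
    bounds = {"alpha": (-7.0, 3.0), "sigma": (-8.0, 8.0), "sigma_se": (-8.0, 8.0),
              "alpha_se": (-12.0, 3.0)}
    if family == "ouosc":
        beta_lo = np.pi / max(ts.duration, 1e-12)
        beta_hi = np.pi / max(ts.median_dt, 1e-12)
        bounds["beta"] = (float(np.log(beta_lo)), float(np.log(beta_hi)))
    return bounds


def _informed_starts(family, ts, bounds):
    """Data-driven initialisations, clipped into the bounds."""
    y = ts.values
    var = max(float(y.var()), 1e-12)
    logvar = float(np.log(var))

    def clip(name, v):
        lo, hi = bounds[name]
        return float(np.clip(v, lo + 1e-9, hi - 1e-9))

    starts = []
    if family in ("ou", "ouosc"):
        alphas = [np.log(1.0), np.log(4.0 / max(ts.duration, 1e-12))]
        betas = []
        if family == "ouosc":
            # periodogram peak as a frequency hint (grid treated as even)
            f, p = scipy.signal.periodogram(y - y.mean(), fs=1.0 / ts.median_dt)
            if f.size > 1 and np.any(p[1:] > 0):
                f_peak = f[1:][int(np.argmax(p[1:]))]
                betas.append(np.log(max(2.0 * np.pi * f_peak, 1e-12)))
            betas.append(0.5 * (bounds["beta"][0] + bounds["beta"][1]))
        for la in alphas:
            if family == "ou":
                starts.append([clip("alpha", la), clip("sigma", logvar)])
            else:
                for lb in betas:
                    starts.append(
                        [clip("alpha", la), clip("beta", lb), clip("sigma", logvar)]
                    )
    else:  # se
        lase = bounds["alpha_se"][1] - 1.0
        starts.append([clip("alpha_se", lase), clip("sigma_se", logvar)])
        starts.append([clip("alpha_se", lase - 3.0), clip("sigma_se", logvar)])
    return starts


def optimize_hyperparameters(
    ts: TimeSeries,
    family: str,
    config: FitConfig | None = None,
    extra_inits: list[np.ndarray] | None = None,
) -> FitResult:
    """Maximise the marginal likelihood over log-hyperparameters.

    Runs L-BFGS-B from ``config.restarts`` randomised starts plus a few
    data-informed ones (and any ``extra_inits`` supplied by the caller,
    given as log-kernel-parameter vectors) and keeps the best local
    optimum.  Deterministic given ``config.seed``.
    """
    if config is None:
        config = FitConfig()
    if family not in _FAMILY_PARAMS:
        raise ValueError(f"unknown kernel family {family!r}")
    if len(ts) < 3:
        raise ValueError("need at least 3 points to fit")

    names = _FAMILY_PARAMS[family]
    bounds = default_bounds(family, ts)
    bounds.update(config.bounds)
    y = ts.values
    var = max(float(y.var()), 1e-12)
    free_noise = config.noise_mode == "free"
    sn2_fixed = float(config.sigma_n_sq)

    box = [bounds[n] for n in names]
    if free_noise:
        box.append((float(np.log(1e-6 * var)), float(np.log(10.0 * var + 1e-300))))

    tau = np.abs(ts.times[:, None] - ts.times[None, :])

    def negative(x):
        lml, grad = _lml_and_grad(y, tau, family, x, free_noise, sn2_fixed)
        return -lml, -grad

    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])

    starts = []
    for s in _informed_starts(family, ts, bounds):
        s = list(s)
        if free_noise:
            s.append(float(np.log(max(0.05 * var, 1e-6 * var * 1.01))))
        starts.append(np.asarray(s))
    if extra_inits:
        for s in extra_inits:
            s = np.asarray(s, dtype=float)
            if free_noise and s.size == len(names):
                s = np.append(s, np.log(max(0.05 * var, 1e-6 * var * 1.01)))
            starts.append(np.clip(s, lo + 1e-9, hi - 1e-9))
    for _ in range(config.restarts):
        starts.append(lo + (hi - lo) * rng.random(len(box)))

    best_x = None
    best_f = np.inf
    best_msg = ""
    n_used = 0
    messages = []
    for x0 in starts:
        n_used += 1
        try:
            # the low-level interface: same algorithm as minimize(method=
            # "L-BFGS-B") without per-call wrapper overhead, which matters
            # when thousands of cells are fitted
            # factr loosened from the 1e7 default: the LLR statistic is
            # consumed at ~1e-3 nat resolution, so ~1e-8 relative
            # convergence of each fit is ample
            xopt, fopt, info = scipy.optimize.fmin_l_bfgs_b(
                negative, x0, bounds=box, maxiter=config.maxiter,
                factr=1e8, pgtol=3e-5,
            )
        except np.linalg.LinAlgError as exc:  # conditioning failure at this start
            messages.append(str(exc))
            continue
        if not np.isfinite(fopt):
            continue
        if fopt < best_f:
            best_f = float(fopt)
            best_x = xopt
            best_msg = str(info.get("task", ""))

    if best_x is None:
        return FitResult(
            family=family,
            params=None,
            noise=NoiseLevel(sn2_fixed),
            log_marginal_likelihood=-np.inf,
            converged=False,
            n_restarts_used=n_used,
            message="; ".join(messages) or "all restarts failed",
        )

    if free_noise:
        theta, sn2 = best_x[:-1], float(np.exp(best_x[-1]))
    else:
        theta, sn2 = best_x, sn2_fixed
    return FitResult(
        family=family,
        params=vector_to_params(family, theta),
        noise=NoiseLevel(sn2),
        log_marginal_likelihood=float(-best_f),
        converged=True,
        n_restarts_used=n_used,
        message=best_msg,
    )


def posterior_mean(ts: TimeSeries, fit: FitResult, query_times) -> np.ndarray:
    """GP predictive mean K_*^T Ky^-1 y at the query times.

    The GP is zero-mean, so the caller is responsible for centring
    ``ts.values`` (and adding the mean back) where appropriate.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    query_times = np.asarray(query_times, dtype=float)
    if not np.all(np.isfinite(query_times)):
        raise ValueError("non-finite query time")
    from .kernels import covariance  # local import to avoid cycle noise

    Ky = build_covariance_matrix(fit.params, ts.times, fit.noise)
    L, _ = cholesky_with_jitter(Ky)
    a = scipy.linalg.cho_solve((L, True), ts.values)
    tau_star = np.abs(query_times[:, None] - ts.times[None, :])
    K_star = covariance(fit.params, tau_star)
    return K_star @ a


def sample_gp(
    params,
    times,
    noise: NoiseLevel | float = 0.0,
    n_samples: int = 1,
    seed: int | np.random.Generator = 0,
) -> list[TimeSeries]:
    """Draw zero-mean GP realisations (plus i.i.d. measurement noise).

    Returns ``n_samples`` :class:`TimeSeries` on the given time grid,
    reproducible for a given seed.
    """
    times = np.asarray(times, dtype=float)
    sn2 = noise.sigma_n_sq if isinstance(noise, NoiseLevel) else float(noise)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = build_covariance_matrix(params, times, 0.0)
    L, _ = cholesky_with_jitter(K + 1e-10 * float(np.mean(np.diag(K))) * np.eye(times.size))
    out = []
    for i in range(n_samples):
        f = L @ rng.standard_normal(times.size)
        if sn2 > 0:
            f = f + rng.normal(0.0, np.sqrt(sn2), times.size)
        out.append(TimeSeries(times, f, cell_id=f"gp_sample_{i}", sigma_n_sq=sn2))
    return out


def fit_result_from_params(params, noise: NoiseLevel | float, lml: float = np.nan) -> FitResult:
    """Wrap known parameters as a converged FitResult (used by simulators
    and the bootstrap)."""
    family, _ = params_to_vector(params)
    sn2 = noise.sigma_n_sq if isinstance(noise, NoiseLevel) else float(noise)
    return FitResult(
        family=family, params=params, noise=NoiseLevel(sn2),
        log_marginal_likelihood=lml, converged=True,
    )
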