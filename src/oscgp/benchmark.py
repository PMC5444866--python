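"""Comparator methods and evaluation harness.

Provides the Lomb-Scargle periodogram test (the standard
frequency-domain alternative, whose null model is white noise),
Benjamini-Hochberg correction for its p-values, cohort-averaged power
spectra, and ROC evaluation of any score against ground-truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from .timeseries import TimeSeries

__all__ = [
    "LombScargleResult",
    "RocCurve",
    "lomb_scargle_test",
    "benjamini_hochberg",
    "average_power_spectrum",
    "roc_curve",
]


@dataclass
class LombScargleResult:
    frequencies: np.ndarray  # cycles per hour
    power: np.ndarray  # classical normalisation: power / sample variance
    min_fap: float  # global false-alarm probability of the highest peak
    oscillatory: bool


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _frequency_grid(ts: TimeSeries, oversample: int = 4) -> np.ndarray:
    T = ts.duration
    n = len(ts)
    f_min = 1.0 / (oversample * T)
    f_max = n / (2.0 * T)  # pseudo-Nyquist for the mean sampling rate
    return np.arange(f_min, f_max + 0.5 * f_min, f_min)


def lomb_scargle_test(
    ts: TimeSeries,
    significance_level: float = 0.05,
    oversample: int = 4,
) -> LombScargleResult:
    """Lomb-Scargle periodogram with a white-noise false-alarm probability.

    The periodogram is evaluated on a grid oversampled ``oversample``-fold
    up to the pseudo-Nyquist frequency and normalised by the sample
    variance, so that under white noise each power is approximately
    Exp(1).  The global FAP of the highest peak uses the standard
    independent-frequency correction 1 - (1 - e^-z)^M with M the number
    of independent frequencies (the grid size divided by the oversampling
    factor).  The cell is flagged oscillatory when that FAP falls below
    ``significance_level``.
    """
    if len(ts) < 8:
        raise ValueError("need at least 8 points for a periodogram test")
    y = ts.values - ts.values.mean()
    var = float(y.var(ddof=1))
    freqs = _frequency_grid(ts, oversample)
    if var == 0:
        power = np.zeros_like(freqs)
        return LombScargleResult(freqs, power, 1.0, False)
    power = scipy.signal.lombscargle(ts.times, y, 2.0 * np.pi * freqs) / var
    z_max = float(power.max())
    m_indep = max(int(round(len(freqs) / oversample)), 1)
    # log1p form keeps precision when e^-z is tiny
    min_fap = float(-np.expm1(m_indep * np.log1p(-min(np.exp(-z_max), 1.0 - 1e-16))))
    return LombScargleResult(freqs, power, min_fap, min_fap < significance_level)


def benjamini_hochberg(pvalues, level: float = 0.05) -> np.ndarray:
    """Step-up FDR correction; returns a boolean pass flag per p-value."""
    pvalues = np.asarray(pvalues, dtype=float)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must be in [0, 1]")
    reject, *_ = multipletests(pvalues, alpha=level, method="fdr_bh")
    return reject


def average_power_spectrum(cohort: list[TimeSeries]) -> tuple[np.ndarray, np.ndarray, float]:
    """Cohort-averaged periodogram on a shared uniform grid.

    Returns (frequency grid in 1/h, mean spectrum, peak frequency
    excluding the zero bin).  Rejects cohorts with mixed time grids.
    """
    if not cohort:
        raise ValueError("empty cohort")
    t0 = cohort[0].times
    for ts in cohort[1:]:
        if len(ts) != len(t0) or not np.allclose(ts.times, t0):
            raise ValueError("cohort must share a common sampling grid")
    dts = np.diff(t0)
    if not np.allclose(dts, dts[0]):
        raise ValueError("sampling grid must be uniform")
    fs = 1.0 / dts[0]
    spectra = []
    for ts in cohort:
        f, p = scipy.signal.periodogram(ts.values - ts.values.mean(), fs=fs)
        spectra.append(p)
    mean_spec = np.mean(spectra, axis=0)
    peak = float(f[1:][int(np.argmax(mean_spec[1:]))])
    return f, mean_spec, peak


def roc_curve(scores, labels) -> RocCurve:
    """ROC curve and trapezoidal AUC of ``scores`` against binary labels
    (1 = oscillatory)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        labels = (labels == "oscillatory").astype(int)
    labels = labels.astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr,
                    auc=float(roc_auc_score(labels, scores)))
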