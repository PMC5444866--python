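"""Numba-compiled inner loops for the delayed Gillespie simulator.

The delayed SSA follows the Barrio-style scheme: a delayed reaction
consumes nothing when it initiates; its state change is queued and
applied at initiation time + delay.  Because the delay is a fixed
constant, completions are processed in FIFO order.  After every state
change (completion or ordinary reaction) the exponential waiting time is
redrawn, which is exact by memorylessness.

Pure-Python fallbacks are selected automatically when numba is absent.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

_QCAP = 1 << 14  # ring-buffer capacity for pending delayed completions


@njit(cache=True)
def _hes1_ssa(mu_m, mu_p, alpha_m_total, alpha_p, p0_omega, h, tau,
              sample_times, seed):
    """Hes1 negative-feedback loop with delayed transcription.

    Reactions: mRNA decay (mu_m * M), protein decay (mu_p * P),
    translation (alpha_p * M), and transcription with Hill repression
    f(P) = alpha_m_total / (1 + (P/(Omega*P0))^h) whose product appears
    only after the delay tau.  ``alpha_m_total`` is the zeroth-order
    transcription propensity in molecules/min, i.e. Omega times the
    concentration-scale rate.  Records the protein count at
    ``sample_times`` (state immediately before the first event past each
    sample time).  All rates and times in minutes.
    """
    np.random.seed(seed)
    n_m = 0
    n_p = 0
    t = 0.0
    queue = np.empty(_QCAP, dtype=np.float64)
    qhead = 0
    qtail = 0
    n_samples = sample_times.shape[0]
    out = np.empty(n_samples, dtype=np.int64)
    si = 0
    while si < n_samples:
        a1 = mu_m * n_m
        a2 = mu_p * n_p
        a3 = alpha_p * n_m
        a4 = alpha_m_total / (1.0 + (n_p / p0_omega) ** h)
        a0 = a1 + a2 + a3 + a4
        if a0 > 0.0:
            t_next = t - np.log(np.random.random()) / a0
        else:
            t_next = np.inf
        if qhead != qtail and queue[qhead % _QCAP] <= t_next:
            t_c = queue[qhead % _QCAP]
            while si < n_samples and sample_times[si] < t_c:
                out[si] = n_p
                si += 1
            t = t_c
            qhead += 1
            n_m += 1
            continue
        if t_next == np.inf:
            while si < n_samples:
                out[si] = n_p
                si += 1
            break
        while si < n_samples and sample_times[si] < t_next:
            out[si] = n_p
            si += 1
        t = t_next
        r = np.random.random() * a0
        if r < a1:
            n_m -= 1
        elif r < a1 + a2:
            n_p -= 1
        elif r < a1 + a2 + a3:
            n_p += 1
        else:
            if tau <= 0.0:
                n_m += 1
            else:
                queue[qtail % _QCAP] = t + tau
                qtail += 1
    return out


@njit(cache=True)
def _bistable_ssa(mu_m, mu_p, alpha_m_total, alpha_p, p0_omega, h,
                  sample_times, seed):
    """Mutual-repression toggle switch: two genes, each transcribed under
    Hill repression by the other's protein; no delay.  Records both
    protein counts at ``sample_times``."""
    np.random.seed(seed)
    m1 = 0
    p1 = 0
    m2 = 0
    p2 = 0
    t = 0.0
    n_samples = sample_times.shape[0]
    out1 = np.empty(n_samples, dtype=np.int64)
    out2 = np.empty(n_samples, dtype=np.int64)
    si = 0
    while si < n_samples:
        a = np.empty(8)
        a[0] = mu_m * m1
        a[1] = mu_p * p1
        a[2] = alpha_p * m1
        a[3] = alpha_m_total / (1.0 + (p2 / p0_omega) ** h)
        a[4] = mu_m * m2
        a[5] = mu_p * p2
        a[6] = alpha_p * m2
        a[7] = alpha_m_total / (1.0 + (p1 / p0_omega) ** h)
        a0 = a.sum()
        if a0 <= 0.0:
            while si < n_samples:
                out1[si] = p1
                out2[si] = p2
                si += 1
            break
        t_next = t - np.log(np.random.random()) / a0
        while si < n_samples and sample_times[si] < t_next:
            out1[si] = p1
            out2[si] = p2
            si += 1
        t = t_next
        r = np.random.random() * a0
        c = 0.0
        j = 0
        for k in range(8):
            c += a[k]
            if r < c:
                j = k
                break
        if j == 0:
            m1 -= 1
        elif j == 1:
            p1 -= 1
        elif j == 2:
            p1 += 1
        elif j == 3:
            m1 += 1
        elif j == 4:
            m2 -= 1
        elif j == 5:
            p2 -= 1
        elif j == 6:
            p2 += 1
        else:
            m2 += 1
    return out1, out2
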