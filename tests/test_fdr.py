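import numpy as np
import pytest

from oscgp.classify import classify_cell
from oscgp.detrend import DetrendConfig
from oscgp.fdr import (
    NullDistribution,
    _allocation,
    classify_at_fdr,
    compute_q_values,
    estimate_pi0,
    generate_bootstrap_null,
)
from oscgp.gp import FitConfig, sample_gp
from oscgp.kernels import OUParams


def brute_force_q(data, null, pi0):
    """Exhaustive minimisation over every cutoff c <= L in the data list."""
    data = np.asarray(data, float)
    null = np.asarray(null, float)
    m, mp = len(data), len(null)
    out = []
    for L in data:
        vals = [
            pi0 * (np.sum(null >= c) / mp) / (np.sum(data >= c) / m)
            for c in data
            if c <= L
        ]
        out.append(min(vals))
    return np.clip(out, 0, 1)


def test_q_values_match_brute_force_on_toy_lists():
    data = [1, 2, 3, 4, 5]
    null = [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
    got = compute_q_values(data, np.asarray(null, float), 1.0)
    assert np.allclose(got, brute_force_q(data, null, 1.0))


@pytest.mark.parametrize("seed", range(5))
def test_q_values_match_brute_force_random(seed):
    rng = np.random.default_rng(seed)
    data = rng.exponential(1.0, 30)
    null = rng.exponential(1.0, 80)
    pi0 = rng.uniform(0.2, 1.0)
    assert np.allclose(compute_q_values(data, null, pi0),
                       brute_force_q(data, null, pi0))


def test_q_value_monotonicity_and_extremes():
    rng = np.random.default_rng(1)
    null = rng.exponential(1.0, 200)
    data = np.concatenate([rng.exponential(1.0, 50), [null.max() + 10.0]])
    q = compute_q_values(data, null, 0.8)
    order = np.argsort(data)
    assert np.all(np.diff(q[order]) <= 1e-12)  # non-increasing in LLR
    assert q[np.argmax(data)] == q.min()
    assert q[np.argmax(data)] == 0.0  # beyond every null draw
    # the other cells keep non-trivial q-values
    assert np.median(q[:-1]) > 0.1
    # pi0 -> 0+ sends all q-values to ~0
    q0 = compute_q_values(data, null, 1e-9)
    assert np.all(q0 < 1e-6)


def test_allocation_equal_split_with_round_robin():
    assert _allocation(2000, 100) == [20] * 100
    assert _allocation(7, 3) == [3, 2, 2]
    assert sum(_allocation(1234, 7)) == 1234


def test_pi0_on_null_only_data():
    rng = np.random.default_rng(2)
    null = rng.exponential(1.0, 2000)
    data = rng.exponential(1.0, 200)
    assert estimate_pi0(data, null) == pytest.approx(1.0, abs=0.15)


def test_pi0_on_half_mixture():
    rng = np.random.default_rng(3)
    null = rng.exponential(1.0, 2000)
    data = np.concatenate([
        rng.exponential(1.0, 100),
        null.max() + 10 + rng.random(100),
    ])
    assert estimate_pi0(data, null) == pytest.approx(0.5, abs=0.15)


def test_pi0_boundary_clamps():
    # all data below every null value at every lambda: clamped above 0
    null = np.linspace(10, 20, 500)
    data = np.linspace(0, 1, 50)
    pi0 = estimate_pi0(data, null)
    assert 0 < pi0 <= 1


def test_classify_at_fdr_threshold_monotone():
    from oscgp.classify import CellResult
    from oscgp.detrend import DetrendResult
    from oscgp.gp import fit_result_from_params
    from oscgp.timeseries import TimeSeries

    def dummy_cell(i):
        fit = fit_result_from_params(OUParams(1, 1), 0.0)
        ts = TimeSeries([0.0, 1.0], [0.0, 0.0])
        det = DetrendResult(fit, np.zeros(2), ts)
        return CellResult(cell_id=f"c{i}", n_points=2, llr_raw=float(i),
                          llr_normalized=float(i), ou_fit=fit, ouosc_fit=fit,
                          detrend=det, period_hours=1.0, q_factor=0.1)

    cells = [dummy_cell(i) for i in range(6)]
    q = np.array([0.6, 0.4, 0.2, 0.06, 0.04, 0.01])
    classify_at_fdr(cells, q, 0.05)
    pass05 = {c.cell_id for c in cells if c.passes}
    classify_at_fdr(cells, q, 0.10)
    pass10 = {c.cell_id for c in cells if c.passes}
    assert pass05 == {"c4", "c5"}
    assert pass05 <= pass10
    # the pass set is an upper set of the LLR ordering
    llrs = {c.cell_id: c.llr_raw for c in cells}
    assert min(llrs[c] for c in pass10) > max(
        llrs[c.cell_id] for c in cells if not c.passes)


def test_bootstrap_null_allocation_and_determinism(grid_25h):
    """The null is reproducible and its LLRs look like data-cell LLRs
    when the data really are OU draws."""
    fc = FitConfig(restarts=2, seed=0, noise_mode="fixed", sigma_n_sq=0.1)
    dc = DetrendConfig(expected_period=12.0)
    sources = []
    for seed in range(4):
        ts = sample_gp(OUParams(0.7, 1.0), grid_25h, 0.1, 1, seed=seed)[0]
        ts.cell_id = f"src{seed}"
        ts.sigma_n_sq = 0.1
        sources.append(classify_cell(ts, dc, fc))
    null_a = generate_bootstrap_null(sources, dc, fc, n_synth=10, seed=9)
    null_b = generate_bootstrap_null(sources, dc, fc, n_synth=10, seed=9)
    assert np.array_equal(null_a.llrs, null_b.llrs)
    assert null_a.m_prime == 10
    # equal allocation across the 4 source cells (10 = 3+3+2+2)
    counts = [null_a.sources.count(c.cell_id) for c in sources]
    assert sorted(counts, reverse=True) == [3, 3, 2, 2]


def test_null_matches_data_distribution_for_true_ou_cells(grid_25h):
    """Two-sample KS between data LLRs and bootstrap LLRs is unremarkable
    when the data generator is itself the null model."""
    from scipy.stats import ks_2samp

    fc = FitConfig(restarts=2, seed=0, noise_mode="fixed", sigma_n_sq=0.1)
    dc = DetrendConfig(expected_period=12.0)
    sources = []
    for seed in range(40):
        ts = sample_gp(OUParams(0.7, 1.0), grid_25h, 0.1, 1, seed=500 + seed)[0]
        ts.sigma_n_sq = 0.1
        sources.append(classify_cell(ts, dc, fc))
    null = generate_bootstrap_null(sources, dc, fc, n_synth=60, seed=1)
    data_llrs = [c.llr_normalized for c in sources]
    assert ks_2samp(data_llrs, null.llrs).pvalue > 0.01
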