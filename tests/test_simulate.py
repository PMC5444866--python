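import numpy as np
import pytest
from scipy.stats import ks_2samp

from oscgp.simulate import (
    BistableParams,
    DelayedNetwork,
    Hes1Params,
    Reaction,
    add_measurement_noise,
    hes1_fixed_point,
    make_benchmark_cohort,
    simulate_bistable,
    simulate_delayed_ssa,
    simulate_hes1,
)
from oscgp.timeseries import TimeSeries


def _birth_death(rate_in, rate_out, delay=0.0):
    return DelayedNetwork(
        species=["X"],
        reactions=[
            Reaction(lambda c: rate_in, [1], delay=delay, name="birth"),
            Reaction(lambda c: rate_out * c[0], [-1], name="death"),
        ],
    )


def test_pure_death_matches_closed_form():
    """Mean count of a pure death process follows N0 * exp(-mu t)."""
    mu = 0.5
    net = DelayedNetwork(species=["X"], reactions=[
        Reaction(lambda c: mu * c[0], [-1], name="death")])
    t_check = 2.0
    finals = []
    for seed in range(200):
        out = simulate_delayed_ssa(net, [1000], 2.5, seed=seed,
                                   sample_times=[0.0, t_check])
        finals.append(out.counts[0, 1])
    expected = 1000 * np.exp(-mu * t_check)
    se = np.std(finals) / np.sqrt(len(finals))
    assert abs(np.mean(finals) - expected) < 3 * se + 1e-9


def test_delayed_ssa_equals_ssa_at_zero_delay():
    """With all delays zero the delayed scheme is distributionally the
    plain SSA (two-sample KS on the count at a fixed time)."""
    t_check = 3.0
    zero_delay, with_queue = [], []
    for seed in range(300):
        out = simulate_delayed_ssa(_birth_death(5.0, 0.4, delay=0.0), [0], 3.5,
                                   seed=seed, sample_times=[t_check])
        zero_delay.append(out.counts[0, 0])
        # delay so small every completion fires before the next event
        out = simulate_delayed_ssa(_birth_death(5.0, 0.4, delay=1e-12), [0], 3.5,
                                   seed=10_000 + seed, sample_times=[t_check])
        with_queue.append(out.counts[0, 0])
    assert ks_2samp(zero_delay, with_queue).pvalue > 0.01


def test_delayed_births_arrive_after_delay():
    net = _birth_death(10.0, 0.0, delay=5.0)
    out = simulate_delayed_ssa(net, [0], 12.0, seed=1,
                               sample_times=[4.9, 6.0, 11.9])
    assert out.counts[0, 0] == 0  # nothing can complete before t = 5
    assert out.counts[0, 2] > out.counts[0, 1] > 0


def test_negative_propensity_raises():
    net = DelayedNetwork(species=["X"], reactions=[
        Reaction(lambda c: -1.0, [1], name="bad birth")])
    with pytest.raises(ValueError, match="bad birth"):
        simulate_delayed_ssa(net, [0], 1.0, seed=0)


def test_hes1_zero_transcription_stays_zero():
    params = Hes1Params(mu_m=0.03, mu_p=0.03, alpha_m=1e-12, alpha_p=1.0,
                        P0=100.0, h=3.0, tau=18.0, Omega=20.0)
    ts = simulate_hes1(params, 600, 30, burn_in=0.0, seed=0)
    assert np.all(ts.values == 0)


def test_hes1_deterministic_given_seed():
    a = simulate_hes1(Hes1Params.oscillatory(), 600, 30, seed=3)
    b = simulate_hes1(Hes1Params.oscillatory(), 600, 30, seed=3)
    c = simulate_hes1(Hes1Params.oscillatory(), 600, 30, seed=4)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)
    # times converted to hours starting at zero
    assert a.times[0] == 0.0
    assert a.times[1] - a.times[0] == pytest.approx(0.5)


def test_hes1_nonoscillatory_mean_matches_fixed_point():
    """Cohort-average protein level within 10% of the deterministic
    fixed point from independent root finding."""
    params = Hes1Params.non_oscillatory()
    target = hes1_fixed_point(params)
    means = [simulate_hes1(params, 1500, 30, seed=s).values.mean()
             for s in range(60)]
    assert abs(np.mean(means) - target) / target < 0.10


def test_low_system_size_counts_right_skewed():
    """At Omega = 1 the oscillatory waveform has peaks larger than
    troughs: pooled counts are right-skewed."""
    from scipy.stats import skew

    pooled = np.concatenate([
        simulate_hes1(Hes1Params.oscillatory(Omega=1.0), 1500, 30, seed=s).values
        for s in range(40)
    ])
    assert skew(pooled) > 0.2


def test_bistable_symmetric_and_bimodal():
    """The toggle locks into a protein-1-high or protein-2-high state;
    which species wins is a fair coin across seeds, and pooled counts are
    bimodal (well-separated low and high states, little mass between)."""
    params = BistableParams()
    p1_wins = []
    pooled1 = []
    for seed in range(60):
        p1, p2 = simulate_bistable(params, 1500, 30, seed=seed)
        p1_wins.append(p1.values.mean() > p2.values.mean())
        pooled1.append(p1.values)
    pooled1 = np.concatenate(pooled1)
    # symmetry: winner proportion consistent with 1/2 (3 sigma ~ 0.19 at n=60)
    assert 0.3 < np.mean(p1_wins) < 0.7
    # bimodality of the pooled marginal
    high = np.quantile(pooled1, 0.9)
    mid = high / 2
    assert np.mean(pooled1 < 0.2 * high) > 0.2  # low state occupied
    assert np.mean(pooled1 > 0.8 * high) > 0.2  # high state occupied
    assert np.mean(np.abs(pooled1 - mid) < 0.2 * high) < 0.1  # valley between


def test_add_measurement_noise_variance():
    rng = np.random.default_rng(0)
    ts = TimeSeries(np.arange(1000.0), rng.normal(0, 1, 1000))
    noisy = add_measurement_noise(ts, 0.1, seed=1)
    assert noisy.sigma_n_sq == pytest.approx(0.1 * ts.values.var())
    assert np.var(noisy.values) == pytest.approx(1.1, abs=0.08)
    same = add_measurement_noise(ts, 0.0, seed=1)
    assert np.array_equal(same.values, ts.values)
    with pytest.raises(ValueError):
        add_measurement_noise(ts, -0.1)


def test_benchmark_cohort_labels_and_metadata():
    ds = make_benchmark_cohort("oscillatory", 5, 25.0, 0.5, 0.1,
                               trend_alpha_se=np.exp(-4), seed=3)
    assert len(ds) == 5
    assert all(ds.labels[c.cell_id] == "oscillatory" for c in ds.cells)
    assert all(c.sigma_n_sq == pytest.approx(0.1) for c in ds.cells)
    assert all(len(c) == 51 for c in ds.cells)
    # standardised signal + unit-variance trend + noise: variance well above 1
    assert np.mean([c.values.var() for c in ds.cells]) > 1.0
    # determinism
    ds2 = make_benchmark_cohort("oscillatory", 5, 25.0, 0.5, 0.1,
                                trend_alpha_se=np.exp(-4), seed=3)
    for a, b in zip(ds.cells, ds2.cells):
        assert np.array_equal(a.values, b.values)
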