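# oscgp

Gaussian-process classification of stochastic oscillations in
single-cell gene-expression time series.

## The problem

Live imaging of gene expression in individual cells (luciferase or
fluorescent reporters, typically sampled every 30 minutes over 10–72
hours) produces short, noisy traces. Expression driven by a genetic
oscillator such as *Hes1* drifts in phase and varies in amplitude from
peak to peak, while non-oscillatory expression still *fluctuates*,
because transcription, translation and degradation are random events
among finite numbers of molecules — and those fluctuations are
correlated in time, not white. Eyeballing traces cannot separate the
two, and periodogram tests calibrated against white noise (e.g.
Lomb–Scargle) misclassify correlated aperiodic fluctuations as rhythms.

`oscgp` implements a statistical test built on the mechanistic
expectation of what both kinds of dynamics look like. Linearising a
stochastic reaction network around its steady state yields a Gaussian
process whose covariance function is, per dynamical mode, either

- **OU (aperiodic null)** K(τ) = σ e^(−ατ) — mean-reverting
  fluctuations with correlation time 1/α, or
- **OUosc (quasi-periodic)** K(τ) = σ e^(−ατ) cos(βτ) — a stochastic
  oscillator with angular frequency β (period 2π/β) whose phase
  coherence decays on timescale 1/α; the coherence is summarised by the
  quality factor **Q = β/(2πα)**.

For each cell the exact GP marginal likelihood is maximised under both
kernels (plus a Gaussian measurement-noise term σₙ²), and the
**log-likelihood ratio** LLR = log p(y|OUosc) − log p(y|OU) scores the
evidence for oscillation. Because the models are nested at β = 0, the
LLR is non-negative; because β = 0 sits on the boundary, its null
distribution is *not* chi-squared, so the threshold is calibrated
empirically:

1. **Detrending.** Long-term trends bury oscillations. Each trace is
   first fitted with a squared-exponential (SE) GP,
   K(τ) = σ_SE e^(−α_SE τ²), whose inverse-squared-lengthscale α_SE is
   bounded above so the trend cannot absorb the oscillation; the
   posterior-mean trend is subtracted. The default bound corresponds to
   a minimum trend lengthscale of 3× the expected period
   (l = 1/√(2α_SE)).
2. **Parametric bootstrap null (Cox test).** Synthetic non-oscillatory
   cells are sampled from each cell's fitted trend + OU + noise model,
   pushed through the identical detrend/classify pipeline, and their
   LLRs form the empirical null.
3. **FDR control.** The fraction of truly non-oscillatory cells π₀ is
   estimated by comparing the lower tails of the data and null LLR
   distributions (natural cubic spline over a cutoff grid), each cell
   gets a Storey-type **q-value** (the minimum estimated FDR over
   rejection thresholds that include it), and cells with q < γ
   (default γ = 0.05) are called oscillatory.

The package also contains the synthetic-data machinery used to validate
all of this: an exact delayed-Gillespie simulator of the Hes1
negative-feedback loop (oscillatory and non-oscillatory parameter
regimes), a bistable mutual-repression toggle, measurement-noise and
trend injection, and a Lomb–Scargle + ROC benchmarking harness.

## Worked example

Simulate a small labelled cohort (8 oscillatory-regime and 8
non-oscillatory-regime Hes1 cells, 25 h at 30-min sampling, 10%
measurement noise) and screen it:

```python
from oscgp import OscillationScreen, Dataset
from oscgp.simulate import make_benchmark_cohort

osc = make_benchmark_cohort("oscillatory", 8, seed=1, id_prefix="hes1")
non = make_benchmark_cohort("non-oscillatory", 8, seed=2, id_prefix="ctrl")
data = Dataset(cells=osc.cells + non.cells)

screen = OscillationScreen(data, expected_period=2.0, n_synth=200)
result = screen.fit(seed=0)
print(result.summary())
```

```
Oscillation screen
==================
cells analysed:        16
usable fits:           16
estimated pi0:         0.517
FDR level gamma:       0.05
cells passing:         8
bootstrap null size:   200
period of passing cells (h): median 2.30, IQR [2.27, 2.47]

cell_id  n_points  llr_normalized  period_hours  q_factor  q_value  passes
 hes1_0        51           27.72         2.283     1.926        0    True
 hes1_1        51            13.7         2.772    0.6941        0    True
 hes1_2        51           11.53         2.318    0.6607        0    True
 hes1_3        51            16.4         2.194     1.231        0    True
 hes1_4        51           31.47          2.26     1.422        0    True
 hes1_5        51           19.22         2.277     1.049        0    True
 hes1_6        51           2.849         2.702    0.3103   0.1379   False
 hes1_7        51           7.708         2.521     0.479  0.01182    True
 ctrl_0        51           5.623          2.45     0.407  0.02585    True
 ctrl_1        51          0.6991         2.256    0.2256   0.3347   False
 ctrl_2        51        0.004304         9.014   0.04445    0.455   False
 ctrl_3        51           1.326         2.233    0.2686   0.2648   False
 ctrl_4        51               0            50   0.00406   0.5171   False
 ctrl_5        51          0.0247         3.433   0.08983    0.455   False
 ctrl_6        51         0.01485         4.616   0.07002    0.455   False
 ctrl_7        51          0.1498         1.968    0.1803    0.455   False
```

Reading the table: `llr_normalized` is the log-likelihood ratio per 100
time points — the oscillators score 3–31, the controls score ≈ 0–1.3
with one excursion. `period_hours` (2π/β̂) recovers the ≈ 2.3 h
quasi-period of the oscillatory regime; for non-passing cells it is the
best-fit value of a model that is not supported and should be ignored.
`q_value` is the minimum FDR at which that cell would be called
oscillatory: at γ = 0.05 the screen passes 7/8 true oscillators plus
one false positive (`ctrl_0`, a correlated-noise excursion that genuinely
looks rhythmic over this short window — exactly the kind of error the
FDR machinery is designed to keep at ~5% of calls). π₀ ≈ 0.52 correctly
estimates that about half the population is non-oscillatory.

There is also a CLI mirroring the library:

```bash
oscgp simulate --regime oscillatory --n-cells 50 --out cohort.csv
oscgp analyze cohort.csv --expected-period 2 --out results.csv
oscgp benchmark cohort.csv --labels cohort.labels.csv --expected-period 2 --out roc.csv
oscgp calibrate cohort.csv --labels cohort.labels.csv --out sweep.csv
```

Input CSV format: first column time in hours, one column per cell,
header row required, blank cells = missing samples.

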