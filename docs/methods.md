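# Methods

This note records the models, numerical choices and validation design
behind `oscgp`, at the level of detail a maintainer or reviewer needs.

## Models

**Kernels.** Three stationary covariance functions over lag
τ = |t − t′| (hours):

| kernel | K(τ) | parameters | role |
|---|---|---|---|
| OU | σ e^(−ατ) | α decay rate (1/h), σ signal variance | aperiodic null |
| OUosc | σ e^(−ατ) cos(βτ) | + β angular frequency (rad/h) | quasi-periodic alternative |
| SE | σ_SE e^(−α_SE τ²) | α_SE (1/h²), σ_SE | smooth trend |

σ is a *variance*: K(0) = σ exactly. Only the cosine part of the
complex-mode covariance is used (no sine term). β is an angular
frequency, so the reported period is 2π/β, and the oscillation quality
factor is Q = β/(2πα): the number of coherent cycles (×2π) before phase
memory decays. The SE parameter maps to a correlation lengthscale
l = 1/√(2 α_SE).

These kernels are the fixed-point limit of the linear-noise
approximation of a chemical reaction network: each eigenmode of the
linearised dynamics contributes an exponentially damped (real
eigenvalue → OU) or damped-oscillatory (complex pair → OUosc)
covariance. The package consumes only these end products; it does not
derive them per network.

**Observation model.** y(t) = f(t) + ε, ε ~ N(0, σₙ²), f a zero-mean GP.
Each series is mean-centred before fitting (detrending makes this nearly
a no-op). The log marginal likelihood, its gradient with respect to
log-hyperparameters, and the posterior mean are computed via Cholesky
factorisation (LAPACK `dpotrf`/`dpotrs`/`dpotri`; never an explicit
inverse). If factorisation fails, jitter of 10⁻⁸ × mean diagonal is
added, escalating tenfold up to 10⁻⁴ before raising; escalations are
logged.

## Fitting

All hyperparameters are optimised in log-space (positivity by
construction) with multi-start L-BFGS-B:

- **Bounds**: log α ∈ [−7, 3]; log σ, log σ_SE ∈ [−8, 8]; log β bounded
  so the period lies in [2 × median sampling interval, 2 × series
  duration] — the lower period bound prevents aliasing, the upper stops
  the oscillatory model from chasing trends. Free noise (when no
  measurement-noise estimate exists) is bounded in
  [10⁻⁶ var(y), 10 var(y)].
- **Starts**: data-informed initialisations (σ from the sample
  variance, α from coarse guesses, β from the periodogram peak) plus
  `restarts` log-uniform random starts (default 10 for single fits; the
  cohort pipeline uses 5 — with the informed starts we observe identical
  optima from 3 upward, and the multimodality risk sits almost entirely
  in β, which the periodogram start covers).
- **Nesting in practice**: the OUosc fit is additionally seeded at the
  OU optimum with β at its lower bound, so the alternative never scores
  below the null by more than a boundary artifact. Because β's lower
  bound is π/duration rather than 0, the OU limit is not exactly
  reachable; residual negative LLRs up to ~0.05 nats occur on strongly
  aperiodic series and are clamped to 0 (larger negatives are logged).
- **Convergence**: `factr = 10⁸` (≈10⁻⁸ relative), `pgtol = 3×10⁻⁵`.
  The LLR is consumed at ~10⁻³-nat resolution, far above this.
- **Noise modes**: for simulated data the injected σₙ² is known and
  fixed; for experimental data it should be fixed from background
  measurements; a free mode exists for exploration. The SE trend fit
  always uses free noise — its "noise" absorbs everything non-smooth
  (oscillation + OU + measurement noise) and is deliberately not reused
  downstream.

## Detrending

Two-stage, never joint (joint optimisation is prone to poor local
optima): fit SE + free noise with α_SE ≤ bound (hard box constraint in
log-space), subtract the SE posterior mean, then fit OU/OUosc to the
residual. The default bound sets the minimum trend lengthscale to 3×
the expected period — tight enough to remove drifts, loose enough to
leave the oscillation band intact (verified by the two-frequency
separation test: with a 7.5 h lengthscale, >80% of a 24 h component's
band power is removed while <20% of a 2.5 h component's is). If the SE
optimisation fails outright the series is mean-centred and flagged.

## Classification and FDR

Per cell: LLR = log ML(OUosc) − log ML(OU) on the detrended, centred
series, clamped at 0; also reported normalised per 100 time points so
records of different lengths are comparable ("length" = number of
samples, not hours — the statistic scales with information content,
which for GP likelihoods grows with sample count).

Wilks' theorem does not apply (β = 0 is a boundary point), so the null
is built by parametric bootstrap: `n_synth` synthetic cells (default
2000; the benchmark studies here use 500), allocated equally across
source cells (remainder round-robin), each the sum of a draw from the
cell's fitted SE trend, a draw from its fitted OU model, and Gaussian
noise at its σₙ², on its own time grid — then detrended and classified
identically to data. π₀ is estimated from
π₀(λ) = [#data < λ]/m ÷ [#null < λ]/m′ over 19 cutoffs spanning the
pooled LLR range (fractions 0.10–1.00 in steps of 0.05; zero-null-count
points dropped), smoothed by an ordinary-least-squares natural cubic
spline with 3 basis degrees of freedom (patsy `cr`) and read off at the
*smallest* λ — for an LLR statistic the lower tail is where oscillators
are absent, the mirror image of the classic p-value construction —
then clamped to [1/m, 1].

q-values follow the Storey construction with the empirical null:
q(L) = min over cutoffs c ≤ L of π₀ · [#null ≥ c]/m′ ÷ [#data ≥ c]/m,
evaluated at the observed data LLRs, prefix-minimised (hence exactly
monotone non-increasing in L) and clamped to [0, 1]. The minimisation
direction matters: minimising over cutoffs *above* L would let a single
cell that exceeds every null draw (common — strong oscillators easily
beat a 500–2000-draw null) pull every q-value to zero. A cell passes at
FDR level γ iff q < γ; the pass set is an upper set of the LLR ordering
by construction.

## Synthetic data

**Delayed SSA.** Exact Gillespie simulation with a pending-completion
queue: a delayed reaction consumes nothing at initiation; its full
stoichiometric change is applied at initiation time + delay. If the
next queued completion precedes the next tentative reaction time, the
completion executes first and the waiting time is redrawn (exact by
memorylessness). A generic pure-Python engine handles arbitrary
networks (and serves as the reference in equivalence tests); the Hes1
and toggle-switch models have numba-compiled cores (~10⁶ events/cell in
a few ms).

**Hes1 loop** (mRNA M, protein P, rates per minute): degradation
μ_m M and μ_p P, translation α_p M, and delayed transcription with
propensity Ω α_m / (1 + (n_p/(Ω P₀))^h) delivering one mRNA after τ
minutes. The Ω prefactor on the zeroth-order transcription propensity
is the standard system-size convention (α_m is a concentration-scale
rate); without it the oscillatory parameter set below has too little
feedback gain to resonate at all — the linearised spectrum then peaks
at ≈0.04 h⁻¹ instead of the documented ≈0.5 h⁻¹.

Regimes (both Ω = 20, burn-in 5000 min from empty initial state):

- *oscillatory*: μ = 0.03, α_m = α_p = 1, P₀ = 100, h = 3, τ = 18 min.
  The deterministic system is a stable focus; the oscillation is a
  noise-induced quasi-cycle whose linear-noise spectrum peaks at
  0.443 h⁻¹ (quasi-period ≈ 2.26 h) — consistent with the ≈2.3–2.7 h
  fitted periods throughout the benchmarks.
- *non-oscillatory*: μ = 0.07, α_m = α_p = 1, P₀ = 300, h = 1, τ = 0.
  Stable node; cohort-mean protein count matches the deterministic
  fixed point (≈2787 at Ω = 20) within stochastic error.

**Toggle switch** (S-curve mutual repression, no delay): two genes with
cross-repressive Hill propensities, μ = 0.3, α_m = α_p = 10, P₀ = 12,
h = 2, Ω = 1. Locks into one-high/one-low states with rare
noise-induced switching; pooled counts are strongly bimodal.

**Cohort assembly.** Each simulated trace is z-scored, then Gaussian
measurement noise with variance = `noise_fraction` × signal variance
(default 10%, i.e. σₙ² = 0.1 on the standardised scale, recorded for
fixed-noise fitting) is added, then optionally a smooth trend drawn
from an SE GP with unit variance and configurable α_SE.
Standardisation is what makes "10% of the signal" and "unit-variance
trend" well defined against molecule counts in the thousands; the LLR
is scale-invariant, so it costs nothing statistically.

What the generator deliberately does *not* emulate: extrinsic
(cell-to-cell) parameter variability, photobleaching-style
multiplicative trends, cell division artefacts, tracking errors, or
non-Gaussian measurement noise. Passing benchmarks therefore certify
the statistical machinery under the stated stochastic-kinetics model of
biological variability, not robustness to every artefact of real
imaging.

## Benchmark studies and their observed operating characteristics

All studies run the full pipeline (detrend → classify → bootstrap →
q-values) at γ = 0.05 against known labels; `scripts/acceptance.py`
recomputes them end-to-end. Problem sizes are scaled to single-core
runtimes of minutes: 200 oscillatory + 300 non-oscillatory cells per
cohort and 500 bootstrap cells (the original study design of this kind
used 1000/1000/2000).

- **Detrending calibration**: trend added at α_SE = e⁻⁴ (lengthscale
  5.2 h); detrend bounds e⁻⁶/e⁻⁴/e⁻². A too-tight bound leaves residual
  trend in the series: across seeds, power drops to ~68–78% while the
  achieved FDR stays conservative (~1–5%), and the *mean* fitted period
  inflates from the ~2.3 h truth to ~2.6–2.9 h (the median stays near
  2.5–2.6; a few percent of cells lock onto the smooth residual trend
  with fitted periods of 10 h and beyond, and drag the mean). The
  matched and loose bounds keep power ~94–97% with achieved FDR of
  ~5–8% — slightly above the nominal 5% because the bootstrap null is
  an imperfect proxy (below).
- **Low system size**: Ω = 1 oscillatory cells have skewed,
  non-Gaussian waveforms (peaks exceed troughs); the screen still
  recovers ~96–99% of them.
- **Bistable mis-specification**: toggle-switch trajectories
  occasionally look rhythmic, but against their own OU bootstrap the
  test turns conservative and passes essentially no cells.
- **Null diagnostics**: the normalised LLRs of trended non-oscillatory
  Gillespie cells sit much closer to the bootstrap null (two-sample KS
  ~0.04–0.14 across seeds at m = 300 data / m′ = 1000 null; a
  two-sample KS statistic at these sizes carries a ~0.05 sampling floor
  even for identical distributions) than the unnormalised statistic
  sits to a χ²(1) reference (one-sample KS ~0.17–0.26 on the classical
  2Δlog L scale; the Δlog L variant is also computed for comparison).
  The residual bootstrap bias is in the conservative direction the FDR
  numbers show: the data LLR distribution is slightly broader than the
  null's, because fitted trend variance is under-recovered (median
  σ̂_SE ≈ 0.7 for a unit-variance trend on 51-point records) and the
  two-species reaction dynamics are only approximately OU.

## Known limitations

- Exact GP inference is O(n³) per likelihood evaluation; fine for
  n ≲ 500 points, no sparse/state-space path is provided.
- One dominant frequency per cell: multi-frequency dynamics are handled
  only insofar as detrending filters the slow component (a sum-of-OUosc
  *model* is out of scope; the simulator can generate such data).
- π₀'s spline-at-min(λ) estimator inherits the coarseness of the
  19-point grid at small m; with < ~10 cells the whole FDR stage is
  unreliable (the pipeline refuses < 3 usable cells).
- The bootstrap null conditions on point estimates of each cell's trend
  and OU parameters; parameter uncertainty is not propagated, which is
  the main source of the few-percent FDR excess.
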