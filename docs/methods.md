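# Methods

This note documents the generative models, the estimators, the scoring
model and the numerical choices made in `tvcbench`, including the places
where the design was genuinely open and what the package chose.

## Generative models

All simulations draw pairs of time series from bivariate Gaussians with
unit variances, so the off-diagonal parameter `r_t` is simultaneously the
covariance and the correlation of the generating distribution at time t.
The default length is T = 10,000 samples, read as BOLD fMRI sampled at
TR = 2 s (a deliberately long scan: the goal is benchmarking estimators,
not imitating a single realistic session).

**Simulation 1 (constant covariance).**  `X_t = α X_{t−1} + ε_t`, ε
bivariate Gaussian with covariance 0.5; `X_0 = ε_0` with no burn-in (the
transient from the origin is negligible over 10⁴ samples).  α defaults to
0.8, a realistic lag-1 autocorrelation for BOLD signals.  The stationary
variance is 1/(1 − α²) ≈ 2.78 per series and the stationary correlation
between the series equals the innovation correlation (0.5), both of which
are verified in tests.

**Simulation 2 (fluctuating covariance).**  `r_t = α_r r_{t−1} + ε_t`,
`ε_t ~ N(μ_r, σ_r)` with the first innovation forced to zero (so r starts
at 0 and drifts to its stationary mean μ_r/(1 − α_r)).  Given the track,
`X_t` is drawn independently per time point.  Defaults μ_r = 0.2,
σ_r ∈ {0.08, 0.1, 0.12}, α_r ∈ {0, 0.25, 0.5}.  Because each data point
is a *single* draw at covariance r_t, no estimator can track r_t
perfectly; the benchmark compares estimators against each other, not
against 1.0.

**Clamping.**  A valid 2×2 correlation matrix requires |r_t| < 1, but a
Gaussian innovation can exceed that.  Every generated track is clamped
into ±0.999 (configurable).  For the default parameters clamping is
essentially never active; if more than 1% of draws are clamped the
generator emits a warning, since the marginal distribution of r_t is then
visibly distorted.

**Simulation 3 (task-like non-stationarity).**  As Simulation 2
(σ_r = 0.1) plus a deterministic mean added to both series: a canonical
double-gamma haemodynamic response
`h(t) = γ(t; 6, 1) − γ(t; 16, 1)/6` sampled at 0, 2, …, 32 s (17
samples), normalized so the sampled kernel sums to one — the convention
of the standard SPM-style implementations — scaled by 10 (peak amplitude
≈ 3.85 signal units, i.e. several times the unit noise SD), padded with
three zeros to 20 samples and tiled end-to-end (500 repetitions at
T = 10,000).  The sum-to-one normalization matters: peak-normalizing the
kernel instead (peak 10) makes the shared mean dominate the global means
and pairwise distances that the jackknife and spatial-distance estimators
rely on, and changes the benchmark's qualitative ranking.  The kernel's
first sample is exactly zero (the double-gamma vanishes at t = 0), so 4
of every 20 samples of the mean track are zero, not 3.

**Simulation 4 (state switching).**  The schedule is built by repeatedly
drawing a duration uniformly from L and then a state mean uniformly from
M = {0.2, 0.6} (duration first, then mean — the documented order makes
runs bit-reproducible), until T points are tiled; the final segment is
truncated at T rather than resampled, which preserves the duration
distribution everywhere else.  `r_t ~ N(μ_state(t), σ_r)`.  Fast
condition L = {2…6}, slow L = {20, 30, 40, 50, 60}.  σ_r defaults to 0.1,
the central value of the Simulation 2/3 grid; with state means 0.2/0.6, a
state noise of SD ~1 would leave almost no recoverable state structure
inside the valid covariance range, so large σ_r values trigger the
clamping warning above.

All generators take a seed (or a `numpy` Generator) and are reproducible
bit-for-bit from (simulation id, parameters, seed).

## Estimators

* **SW-w** — Pearson correlation in a centered window of odd length w
  (15 and 29 by default; odd so the window centers on a time point).
  The ⌊w/2⌋ edge points on each side are invalid; with w = 29 and
  T = 10,000 all methods share 9,972 valid points.
* **TSW-w** — weighted Pearson correlation with Gaussian weights centered
  on the window midpoint, zero outside the window.  The taper width is a
  Gaussian SD of 10 time points by default.  This is the reading of a
  "Gaussian taper of 10" that reproduces the Simulation-1 similarity
  structure between tapered and untapered windows; treating 10 as the
  *variance* (SD ≈ 3.2) collapses a 29-point window to an effective ~13
  points and breaks that structure.  Implemented by convolving the
  weighted moment sums with the fixed kernel — identical (to float
  precision, tested) to evaluating the weighted correlation per window.
* **SD** — for each time point t, weights `w_u(t) = 1/‖X_t − X_u‖` (u ≠ t)
  over the amplitude vectors, min–max scaled to [0, 1] over the whole
  off-diagonal weight matrix, self weight set to 1 afterwards; the
  estimate is the weighted Pearson correlation under w(t).  Global (not
  per-time-point) scaling is the variant that matches the method's
  published similarity with the jackknife estimator (ρ ≈ 0.976 on
  Simulation-1 data; per-row scaling gives ≈ 0.93).  Coincident
  amplitude vectors (zero distance, u ≠ t) receive the largest finite
  weight.  Bivariate mode computes weights from the two series of the
  edge; multivariate mode computes one shared weight set from all R
  series and estimates every edge under it.  O(T²) time, O(T·chunk)
  memory.
* **JC** — minus the Pearson correlation of all points except t, with
  means recomputed per exclusion.  The sign flip makes the estimate track
  local covariance positively.  Computed in O(T) from leave-one-out
  sufficient statistics; a brute-force O(T²) evaluation is kept as a test
  oracle (agreement < 1e−10).  The generalization `leave_n_out` excludes
  the n consecutive points centered on t, shifting the block inward at
  the series edges so exactly T − n points always remain; n = 1 is the
  jackknife.
* **MTD-s** — product of first differences divided by the product of the
  *overall* derivative SDs (the normalizing SDs carry no time index),
  then a centered boxcar mean of length s (default 7; the simplest
  reading of "window smoothing", and the one used by the method's
  original description).  Product scale: not bounded by ±1 and exempt
  from the Fisher transform.

**Post-processing.**  Correlation-scale estimates are Fisher-transformed
(`atanh`, inputs capped at 1 − 1e−12); all estimates entering the
tracking model are standardized to zero mean and unit population SD over
the common valid mask.  Standardization uses the population convention
(divide by N) — immaterial at N ≈ 10⁴ but fixed for reproducibility.

## Scoring

**Similarity (Simulation 1).**  Pairwise Spearman ρ over the common mask.
Spearman is rank-based, so the Fisher transform and standardization do
not affect it; the jackknife series is deliberately left unstandardized
here to display its variance compression.

**Tracking model (Simulations 2–4).**  `y_i ~ N(α + β x_i, σ)` with
α, β ~ N(0, 1) and σ ~ HalfNormal(0, 1), where y is the standardized true
r_t and x one estimator's standardized output.  Sampled with an in-package
No-U-Turn sampler (slice-based dynamic HMC, dual-averaging step-size
adaptation targeting 0.8 acceptance, max tree depth 10, identity mass
matrix — adequate because all three posterior scales are ~n^{−1/2}).
σ is sampled as log σ with the Jacobian term.  The Gaussian likelihood
reduces to six sufficient statistics of (x, y), so each gradient is O(1)
and a full 2 × 5,500-draw fit takes under a second.  Default: 2 chains,
5,500 draws each, first 500 discarded (the adaptation window).  Split
R-hat of the slope > 1.01 or any divergent transition raises a warning
(never an error); diagnostics are recorded in the report.  The sampler is
validated in tests against the closed-form OLS solution (the posterior
mode under these weak priors), against an independent ensemble MCMC
implementation, and on a known Gaussian target.

**WAIC.**  Deviance scale: `WAIC = −2 Σ_i (lppd_i − p_i)` with
`lppd_i = log mean_d p(y_i | θ_d)` and `p_i = Var_d log p(y_i | θ_d)`;
`SE = sqrt(N · Var_i)` of the pointwise contributions (sample variance).
The pointwise log-likelihood matrix (10⁴ draws × ~10⁴ points ≈ 0.8 GB) is
never materialized: it is evaluated in draw chunks as a rank-6 matrix
product of per-draw coefficients with the observation monomials, with a
log-sum-exp guard and log-likelihoods centered at the posterior-mean
parameters before second-moment accumulation.  Agreement with a literal
brute-force evaluation (< 1e−8) and with `arviz` is tested.

**Posterior summaries.**  Slope mean, SD, equal-tailed 95% interval,
fraction of draws above zero, and mode (Gaussian KDE with Silverman
bandwidth, argmax on a 512-point grid).

## Orchestration

`run_benchmark` iterates the condition grid (1 similarity condition, 9
fluctuating-covariance, 3 task-like, 2 state-switching = 15 conditions).
Per-condition seeds derive from the master seed via `SeedSequence` spawn
keys, so conditions are independent and reorderable, and the whole run is
deterministic given the master seed.  Per-method failures (e.g. a
constant estimate that cannot be standardized) are captured in the
report's `failures` field without aborting the run.  User estimators are
smoke-tested on a 100-point fixture at registration; the original
package's network submission mechanism is replaced by a local report
bundle (JSON + CSV tables).

## Problem sizes in the test suite

Value checks against published WAIC tables use the full study conditions
(T = 10,000; 2 × 5,500 draws).  Rank and ordinal checks (which compare
WAIC *orderings*, insensitive to the number of posterior draws) use
2 × 450 draws with 200 burned, and the multi-replicate parameter-recovery
and oracle checks use shorter series (T = 1,000–5,000) — the package's
own choice of the smallest sizes at which the assertions are stable.

## Known limitations

* The simulations share one noise model (Gaussian, unit variance, at most
  lag-1 signal autocorrelation); real fMRI adds measurement noise,
  frequency-structured autocorrelation, motion artefacts and more than
  two regions.  Passing the benchmark shows covariance tracking under the
  stated models, nothing stronger.
* Only pairwise estimation is implemented for SW/TSW/JC/MTD; the
  spatial-distance estimator additionally offers the multivariate weight
  variant.
* The mean of the slow state-switching condition's published absolute
  WAIC for the tapered window could not be matched by any parameter
  reading consistent with the rest of the published tables (our value is
  ~6% higher); the qualitative ranking claims all reproduce.  See the
  test suite for the exact tolerances checked.
* WAIC standard errors use the sample-variance convention; other
  conventions differ by O(1/N) factors.
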