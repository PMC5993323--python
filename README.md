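# tvcbench

Simulation benchmarks for **time-varying connectivity (TVC)** estimators.

Many methods exist for estimating per-time-point statistical dependence
between a pair of signals (sliding-window correlations, derivative
products, distance-weighted correlations, jackknife estimates, ...), and
applied work in functional neuroimaging mixes them freely even though the
ground truth of brain connectivity dynamics is unknown.  `tvcbench`
provides a controlled alternative: it simulates pairs of time series from
bivariate Gaussians whose covariance parameter `r_t` is **known at every
time point**, runs a set of TVC estimators on them, and scores how well
each estimator tracks `r_t`.  Researchers can register their own estimator
and benchmark it against the built-ins under identical conditions.

## The benchmark

Four generative regimes (T = 10,000 points each, emulating BOLD fMRI at
TR = 2 s):

1. **Constant covariance, autocorrelated signals** — `X_t = α X_{t−1} + ε_t`
   with ε bivariate Gaussian (unit variances, covariance 0.5, α = 0.8).
   Used to measure how similar the estimators are to each other
   (pairwise Spearman ρ).
2. **Fluctuating covariance** — `X_t ~ N(0, [[1, r_t], [r_t, 1]])` with
   `r_t = α r_{t−1} + ε_t`, `ε ~ N(μ_r, σ_r)` (μ_r = 0.2,
   σ_r ∈ {0.08, 0.1, 0.12}, α ∈ {0, 0.25, 0.5}).
3. **Fluctuating covariance + task-like non-stationarity** — as (2) with a
   canonical haemodynamic response repeated every 20 samples added to the
   mean of both series.
4. **State switching** — `r_t ~ N(μ_state(t), σ_r)` where μ_state jumps
   between {0.2, 0.6} with random durations (fast: 2–6 points; slow:
   20–60 points).

Built-in estimators: sliding window (SW-15, SW-29), Gaussian-tapered
sliding window (TSW-15, TSW-29), spatial-distance weighted correlation
(SD), jackknife (leave-one-out) correlation (JC), and multiplication of
temporal derivatives (MTD-7).

Tracking ability is scored with a Bayesian linear model fitted by NUTS
(No-U-Turn sampler; 2 chains × 5,500 draws, 500 burned):

```
y_i ~ N(α + β x_i, σ),   α ~ N(0,1),  β ~ N(0,1),  σ ~ HalfNormal(0,1)
```

where `y` is the standardized true covariance `r_t` and `x` the
standardized estimator output over the 9,972-point mask common to all
methods.  Models are compared by **WAIC** (deviance scale, lower = better)
and by the posterior of the tracking slope β.

## Worked example

```python
import tvcbench

# fluctuating covariance, no autocorrelation on r_t
ds = tvcbench.simulate_sim2(T=10_000, sigma_r=0.1, alpha_r=0.0, seed=1)

jc = tvcbench.jackknife_correlation(ds.pair.values)
sw = tvcbench.sliding_window(ds.pair.values, tvcbench.WindowSpec(29))
mask = tvcbench.common_valid_mask([jc, sw])
print(mask.sum())                          # 9972

x = tvcbench.standardize(tvcbench.fisher_transform(jc), mask).masked(mask)
y = ds.truth.r[mask]
y = (y - y.mean()) / y.std()

fit = tvcbench.fit_tracking_model(x, y, tvcbench.TrackingModelSpec(seed=1))
w, se = tvcbench.waic(fit)
print(round(w, 1), round(se, 1))           # 28184.0 143.0
s = tvcbench.posterior_summary(fit)
print(round(s.mean, 3), s.frac_gt0)        # 0.11 1.0
```

The jackknife estimator explains a slope of ≈ 0.11 of the standardized
covariance fluctuations and its entire slope posterior is above zero; the
WAIC of ≈ 2.82 × 10⁴ on 9,972 points is the reference value windowed
methods fail to reach in this condition.

The full grid runs from the command line:

```bash
tvcbench run --out results/ --quick      # reduced sizes, minutes
tvcbench run --out results/              # full benchmark
tvcbench simulate --sim 2 --seed 1 --out data/
tvcbench report results/                 # re-render CSV tables
```

Reports are written as `report.json` plus per-condition CSV tables
(WAIC, ΔWAIC, posterior-β summaries, similarity matrix).

## Registering your own estimator

```python
import tvcbench

def my_method(values, **params):           # values: (T, 2) array
    estimate, valid = ...                  # per-time-point estimate + mask
    return estimate, valid

tvcbench.register_method("mine", my_method)
report = tvcbench.run_benchmark()          # "mine" scored alongside built-ins
```

A method that cannot be scored (e.g. constant output) is reported as
failed for that condition without aborting the run.

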