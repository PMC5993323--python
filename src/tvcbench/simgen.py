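"""Generators for the four benchmark simulations.

All simulations produce pairs of time series sampled from bivariate
Gaussians whose covariance parameter ``r_t`` is known at every time point,
so that time-varying connectivity (TVC) estimators can be scored against
ground truth:

* Simulation 1 — constant covariance with AR(1) signal autocorrelation
  (method-similarity benchmark; no fluctuating truth).
* Simulation 2 — ``r_t`` fluctuates as Gaussian noise, optionally with an
  AR(1) structure on the covariance itself.
* Simulation 3 — as Simulation 2, plus a repeated haemodynamic-response
  shaped mean (a non-stationarity mimicking task fMRI).
* Simulation 4 — ``r_t`` switches between discrete covariance states with
  random durations (fast or slow transitions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, stats

__all__ = [
    "BivariatePair",
    "CovarianceTrack",
    "StateSchedule",
    "HRFKernel",
    "SimulatedDataset",
    "simulate_sim1",
    "sample_fluctuating_covariance",
    "simulate_with_track",
    "canonical_hrf",
    "build_hrf_mean_track",
    "sample_state_covariance",
    "simulate_sim2",
    "simulate_sim3",
    "simulate_sim4",
    "ar1_filter",
    "FAST_DURATIONS",
    "SLOW_DURATIONS",
    "DEFAULT_STATE_MEANS",
]

#: State-duration sets for Simulation 4 (in time points; TR = 2 s assumed,
#: so these correspond to 4-12 s and 40-120 s state lifetimes).
FAST_DURATIONS = (2, 3, 4, 5, 6)
SLOW_DURATIONS = (20, 30, 40, 50, 60)
#: Covariance state means for Simulation 4.
DEFAULT_STATE_MEANS = (0.2, 0.6)

#: Default clamp bound keeping r_t strictly inside (-1, 1).
DEFAULT_CLAMP = 0.999


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class BivariatePair:
    """Two aligned time series of length T (columns of ``values``)."""

    values: np.ndarray  # (T, 2)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 2:
            raise ValueError("values must be a T x 2 matrix")
        if values.shape[0] < 2:
            raise ValueError("need at least two time points")
        if not np.isfinite(values).all():
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", values)

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.values[:, 1]


@dataclass(frozen=True)
class CovarianceTrack:
    """Per-time-point covariance parameter ``r_t`` with its generator params.

    With unit variances the 2x2 covariance [[1, r_t], [r_t, 1]] is positive
    definite iff |r_t| < 1, which the clamp bound guarantees.
    """

    r: np.ndarray
    mu_r: float = 0.0
    sigma_r: float = 0.0
    alpha_r: float = 0.0
    clamp_bound: float = DEFAULT_CLAMP

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 1 or r.size < 1:
            raise ValueError("r must be a non-empty vector")
        if np.abs(r).max() >= 1:
            raise ValueError("|r_t| must be < 1 for a valid covariance")
        object.__setattr__(self, "r", r)

    @property
    def T(self) -> int:
        return self.r.size


@dataclass(frozen=True)
class StateSchedule:
    """Tiling of [0, T) into covariance states.

    ``segments`` is an ordered list of (start, duration, state_mean); the
    last segment may be truncated at T.
    """

    segments: tuple
    state_means: tuple
    duration_set: tuple

    def mean_track(self, T: int) -> np.ndarray:
        mu = np.empty(T)
        for start, dur, m in self.segments:
            mu[start : start + dur] = m
        return mu

    def validate(self, T: int) -> None:
        pos = 0
        for start, dur, m in self.segments:
            if start != pos or dur < 1:
                raise ValueError("segments must tile [0, T) without gaps")
            if m not in self.state_means:
                raise ValueError("segment mean not in state-mean set")
            pos = start + dur
        if pos != T:
            raise ValueError("segments do not cover [0, T)")


@dataclass(frozen=True)
class HRFKernel:
    """A sampled haemodynamic response, peak-scaled and zero-padded."""

    samples: np.ndarray
    tr: float
    peak_scale: float = 10.0

    @property
    def length(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class SimulatedDataset:
    """A generated pair plus everything needed to score estimators on it."""

    pair: BivariatePair
    truth: CovarianceTrack | None = None
    mean_track: np.ndarray | None = None
    schedule: StateSchedule | None = None

    def __post_init__(self):
        if self.truth is not None and self.truth.T != self.pair.T:
            raise ValueError("truth and pair lengths differ")
        if self.mean_track is not None and len(self.mean_track) != self.pair.T:
            raise ValueError("mean_track and pair lengths differ")

    @property
    def T(self) -> int:
        return self.pair.T


# ---------------------------------------------------------------------------
# Helpers


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def ar1_filter(eps: np.ndarray, alpha: float) -> np.ndarray:
    """Recursion ``z_t = alpha * z_{t-1} + eps_t`` with ``z_0 = eps_0``."""
    return signal.lfilter([1.0], [1.0, -alpha], eps, axis=0)


def _clamp(r: np.ndarray, bound: float) -> np.ndarray:
    clipped = np.clip(r, -bound, bound)
    frac = np.mean(clipped != r)
    if frac > 0.01:
        warnings.warn(
            f"{frac:.1%} of covariance draws fell outside [-{bound}, {bound}] "
            "and were clamped; consider a smaller sigma_r",
            stacklevel=3,
        )
    return clipped


# ---------------------------------------------------------------------------
# Simulation 1


def simulate_sim1(
    T: int = 10_000, alpha: float = 0.8, cov: float = 0.5, seed=None
) -> SimulatedDataset:
    """Constant-covariance AR(1) pair.

    ``X_t = alpha * X_{t-1} + eps_t`` with eps bivariate Gaussian, zero
    mean, unit variances and off-diagonal ``cov``; ``X_0 = eps_0``.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1) for stationarity")
    if abs(cov) >= 1:
        raise ValueError("|cov| must be < 1")
    rng = _rng(seed)
    z = rng.standard_normal((T, 2))
    eps = np.empty_like(z)
    eps[:, 0] = z[:, 0]
    eps[:, 1] = cov * z[:, 0] + np.sqrt(1 - cov**2) * z[:, 1]
    values = ar1_filter(eps, alpha)
    meta = {"sim": 1, "T": T, "alpha": alpha, "cov": cov, "seed": seed}
    return SimulatedDataset(
        pair=BivariatePair(values, meta=meta), mean_track=np.zeros(T)
    )


# ---------------------------------------------------------------------------
# Simulation 2 building blocks


def sample_fluctuating_covariance(
    T: int,
    mu_r: float = 0.2,
    sigma_r: float = 0.1,
    alpha_r: float = 0.0,
    clamp_bound: float = DEFAULT_CLAMP,
    seed=None,
) -> CovarianceTrack:
    """Draw ``r_t = alpha_r * r_{t-1} + eps_t`` with eps ~ N(mu_r, sigma_r).

    The innovation at t = 0 is forced to 0 (so r_0 = 0), and every r_t is
    clamped into [-clamp_bound, clamp_bound].  With alpha_r > 0 the
    stationary mean is mu_r / (1 - alpha_r).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if sigma_r <= 0:
        raise ValueError("sigma_r must be > 0")
    if not 0 <= alpha_r < 1:
        raise ValueError("alpha_r must be in [0, 1)")
    if not 0 < clamp_bound <= 1:
        raise ValueError("clamp_bound must be in (0, 1]")
    rng = _rng(seed)
    eps = rng.normal(mu_r, sigma_r, size=T)
    eps[0] = 0.0
    r = _clamp(ar1_filter(eps, alpha_r), clamp_bound)
    return CovarianceTrack(r, mu_r=mu_r, sigma_r=sigma_r, alpha_r=alpha_r,
                           clamp_bound=clamp_bound)


def simulate_with_track(
    track: CovarianceTrack, mean_track: np.ndarray | None = None, seed=None
) -> SimulatedDataset:
    """Sample ``X_t ~ N((mu_t, mu_t), [[1, r_t], [r_t, 1]])`` independently per t."""
    T = track.T
    if mean_track is None:
        mean_track = np.zeros(T)
    mean_track = np.asarray(mean_track, dtype=float)
    if mean_track.shape != (T,):
        raise ValueError("mean_track length must match the covariance track")
    rng = _rng(seed)
    z = rng.standard_normal((T, 2))
    r = track.r
    values = np.empty((T, 2))
    values[:, 0] = z[:, 0] + mean_track
    values[:, 1] = r * z[:, 0] + np.sqrt(1 - r**2) * z[:, 1] + mean_track
    meta = {"mu_r": track.mu_r, "sigma_r": track.sigma_r,
            "alpha_r": track.alpha_r, "seed": seed}
    return SimulatedDataset(
        pair=BivariatePair(values, meta=meta), truth=track, mean_track=mean_track
    )


# ---------------------------------------------------------------------------
# Simulation 3: HRF mean track


def canonical_hrf(tr: float = 2.0, peak_scale: float = 10.0) -> HRFKernel:
    """Canonical double-gamma haemodynamic response sampled every ``tr`` s.

    h(t) = gamma.pdf(t; 6) - gamma.pdf(t; 16) / 6 over a 32 s support
    (17 samples at tr = 2), normalized so the sampled kernel sums to one
    (the convention of the standard SPM-style implementations), multiplied
    by ``peak_scale`` and padded with three trailing zeros.  With the
    defaults the peak amplitude is ~3.85 signal units.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    t = np.arange(0.0, 32.0 + 1e-9, tr)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    h = h / h.sum() * peak_scale
    samples = np.concatenate([h, np.zeros(3)])
    return HRFKernel(samples=samples, tr=tr, peak_scale=peak_scale)


def build_hrf_mean_track(T: int, kernel: HRFKernel) -> np.ndarray:
    """Tile the kernel end-to-end and truncate at T."""
    if T < 1:
        raise ValueError("T must be >= 1")
    reps = -(-T // kernel.length)
    return np.tile(kernel.samples, reps)[:T]


# ---------------------------------------------------------------------------
# Simulation 4: state-switching covariance


def sample_state_covariance(
    T: int,
    M: Sequence[float] = DEFAULT_STATE_MEANS,
    L: Sequence[int] = SLOW_DURATIONS,
    sigma_r: float = 0.1,
    clamp_bound: float = DEFAULT_CLAMP,
    seed=None,
) -> tuple[CovarianceTrack, StateSchedule]:
    """State-switching covariance: durations uniform over L, means uniform over M.

    For each segment a duration is drawn first, then a state mean (both
    uniformly); ``r_t ~ N(mu_state(t), sigma_r)`` clamped into the valid
    covariance range.  The final segment is truncated at T.
    """
    M = tuple(sorted(set(float(m) for m in M)))
    L = tuple(sorted(set(int(d) for d in L)))
    if not M or not L:
        raise ValueError("M and L must be non-empty")
    if any(abs(m) >= 1 for m in M):
        raise ValueError("state means must lie in (-1, 1)")
    if any(d < 1 for d in L):
        raise ValueError("durations must be >= 1")
    if sigma_r <= 0:
        raise ValueError("sigma_r must be > 0")
    rng = _rng(seed)
    segments = []
    pos = 0
    while pos < T:
        dur = int(rng.choice(L))
        mean = float(rng.choice(M))
        dur = min(dur, T - pos)
        segments.append((pos, dur, mean))
        pos += dur
    schedule = StateSchedule(segments=tuple(segments), state_means=M, duration_set=L)
    mu_state = schedule.mean_track(T)
    r = _clamp(rng.normal(mu_state, sigma_r), clamp_bound)
    track = CovarianceTrack(r, mu_r=float(np.mean(M)), sigma_r=sigma_r,
                            alpha_r=0.0, clamp_bound=clamp_bound)
    return track, schedule


# ---------------------------------------------------------------------------
# Convenience wrappers (one per benchmark simulation)


def simulate_sim2(
    T: int = 10_000,
    mu_r: float = 0.2,
    sigma_r: float = 0.1,
    alpha_r: float = 0.0,
    clamp_bound: float = DEFAULT_CLAMP,
    seed=None,
) -> SimulatedDataset:
    """Fluctuating-covariance pair (zero mean)."""
    rng = _rng(seed)
    track = sample_fluctuating_covariance(T, mu_r, sigma_r, alpha_r, clamp_bound, rng)
    ds = simulate_with_track(track, seed=rng)
    ds.pair.meta.update({"sim": 2, "T": T, "mu_r": mu_r, "sigma_r": sigma_r,
                         "alpha_r": alpha_r, "seed": seed})
    return ds


def simulate_sim3(
    T: int = 10_000,
    mu_r: float = 0.2,
    sigma_r: float = 0.1,
    alpha_r: float = 0.0,
    tr: float = 2.0,
    clamp_bound: float = DEFAULT_CLAMP,
    seed=None,
) -> SimulatedDataset:
    """As Simulation 2 but with a repeated HRF-shaped mean on both series."""
    rng = _rng(seed)
    track = sample_fluctuating_covariance(T, mu_r, sigma_r, alpha_r, clamp_bound, rng)
    mean_track = build_hrf_mean_track(T, canonical_hrf(tr))
    ds = simulate_with_track(track, mean_track=mean_track, seed=rng)
    ds.pair.meta.update({"sim": 3, "T": T, "mu_r": mu_r, "sigma_r": sigma_r,
                         "alpha_r": alpha_r, "tr": tr, "seed": seed})
    return ds


def simulate_sim4(
    T: int = 10_000,
    condition: str = "slow",
    M: Sequence[float] = DEFAULT_STATE_MEANS,
    sigma_r: float = 0.1,
    clamp_bound: float = DEFAULT_CLAMP,
    seed=None,
) -> SimulatedDataset:
    """State-switching covariance pair (fast: 2-6 point states; slow: 20-60)."""
    if condition not in ("fast", "slow"):
        raise ValueError("condition must be 'fast' or 'slow'")
    L = FAST_DURATIONS if condition == "fast" else SLOW_DURATIONS
    rng = _rng(seed)
    track, schedule = sample_state_covariance(T, M, L, sigma_r, clamp_bound, rng)
    ds = simulate_with_track(track, seed=rng)
    ds.pair.meta.update({"sim": 4, "T": T, "condition": condition,
                         "sigma_r": sigma_r, "seed": seed})
    return SimulatedDataset(pair=ds.pair, truth=ds.truth,
                            mean_track=ds.mean_track, schedule=schedule)
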