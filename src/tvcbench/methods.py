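"""Time-varying connectivity estimators and shared post-processing.

Five estimators are provided, spanning the main families used for
per-time-point connectivity in fMRI:

* ``sliding_window`` (SW) — Pearson correlation in a centered window.
* ``tapered_sliding_window`` (TSW) — Gaussian-weighted Pearson correlation.
* ``spatial_distance_tvc`` (SD) — weighted Pearson correlation where each
  time point's weights are the scaled inverse Euclidean distances between
  amplitude vectors.
* ``jackknife_correlation`` (JC) — sign-flipped leave-one-out Pearson
  correlation assigned to the left-out point.
* ``mtd`` — multiplication of temporal derivatives with boxcar smoothing.

Post-processing shared by the benchmark: Fisher transform (correlation
methods only), standardization and a common valid-time-point mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simgen import BivariatePair

__all__ = [
    "TVCSeries",
    "WindowSpec",
    "DegenerateSeriesError",
    "weighted_pearson",
    "sliding_window",
    "tapered_sliding_window",
    "spatial_distance_tvc",
    "jackknife_correlation",
    "leave_n_out_correlation",
    "mtd",
    "fisher_transform",
    "standardize",
    "common_valid_mask",
]

_FISHER_CAP = 1.0 - 1e-12


class DegenerateSeriesError(ValueError):
    """Raised when an estimate is undefined (zero variance under the weights)."""


@dataclass(frozen=True)
class WindowSpec:
    """A centered window; ``taper_std`` (in time points) enables the Gaussian taper."""

    length: int
    taper_std: float | None = None

    def __post_init__(self):
        if self.length < 3 or self.length % 2 == 0:
            raise ValueError("window length must be an odd integer >= 3 "
                             "so the window centers on a time point")
        if self.taper_std is not None and self.taper_std <= 0:
            raise ValueError("taper_std must be > 0")


@dataclass(frozen=True)
class TVCSeries:
    """One method's per-time-point connectivity estimate.

    ``estimate`` holds the raw values (NaN where invalid); ``valid`` marks
    the time points the method can estimate.  ``correlation_scale`` is True
    for methods whose raw estimates are correlations in [-1, 1] (SW, TSW,
    SD, JC) and False for product-scale couplings (MTD).
    """

    estimate: np.ndarray
    valid: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    correlation_scale: bool = True

    def __post_init__(self):
        est = np.asarray(self.estimate, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        if est.shape != valid.shape or est.ndim != 1:
            raise ValueError("estimate and valid must be 1-D and congruent")
        if not np.isfinite(est[valid]).all():
            raise ValueError("estimates must be finite on valid points")
        object.__setattr__(self, "estimate", est)
        object.__setattr__(self, "valid", valid)

    @property
    def T(self) -> int:
        return self.estimate.size

    def masked(self, mask: np.ndarray) -> np.ndarray:
        """Estimates restricted to ``mask`` (which must be within ``valid``)."""
        if np.any(mask & ~self.valid):
            raise ValueError("mask includes points this method did not estimate")
        return self.estimate[mask]


def _as_values(pair) -> np.ndarray:
    if isinstance(pair, BivariatePair):
        return pair.values
    values = np.asarray(pair, dtype=float)
    if values.ndim != 2 or values.shape[1] != 2:
        raise ValueError("expected a BivariatePair or T x 2 matrix")
    return values


# ---------------------------------------------------------------------------
# Weighted Pearson correlation


def weighted_pearson(x, y, w) -> float:
    """Pearson correlation with nonnegative observation weights.

    Uses weighted means; uniform weights reduce to the plain Pearson
    correlation, and zero weights exclude points entirely.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != y.shape or x.shape != w.shape:
        raise ValueError("x, y, w must have the same length")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if np.count_nonzero(w) < 2:
        raise DegenerateSeriesError("need at least two positive weights")
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    dx = x - mx
    dy = y - my
    cov = (w * dx * dy).sum() / wsum
    vx = (w * dx * dx).sum() / wsum
    vy = (w * dy * dy).sum() / wsum
    if vx <= 0 or vy <= 0:
        raise DegenerateSeriesError("zero weighted variance")
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


# ---------------------------------------------------------------------------
# Sliding windows


def sliding_window(pair, window: WindowSpec | int) -> TVCSeries:
    """Pearson correlation in a window of odd length centered on each t."""
    if isinstance(window, int):
        window = WindowSpec(window)
    if window.taper_std is not None:
        raise ValueError("use tapered_sliding_window for tapered windows")
    values = _as_values(pair)
    T = values.shape[0]
    L = window.length
    if L > T:
        raise ValueError("window longer than series")
    x = pd.Series(values[:, 0])
    y = pd.Series(values[:, 1])
    est = x.rolling(L, center=True, min_periods=L).corr(y).to_numpy()
    half = L // 2
    valid = np.zeros(T, dtype=bool)
    valid[half : T - half] = True
    est = np.where(valid, np.clip(est, -1.0, 1.0), np.nan)
    if not np.isfinite(est[valid]).all():
        raise DegenerateSeriesError("constant window encountered")
    return TVCSeries(est, valid, method=f"SW-{L}", params={"length": L})


def _taper_weights(length: int, taper_std: float) -> np.ndarray:
    k = np.arange(length) - length // 2
    return np.exp(-0.5 * (k / taper_std) ** 2)


def tapered_sliding_window(pair, window: WindowSpec) -> TVCSeries:
    """Gaussian-tapered sliding window (weighted Pearson correlation).

    Each in-window point is weighted by a Gaussian density centered on the
    window midpoint with standard deviation ``taper_std`` time points; the
    weights are zero outside the window.  Implemented by convolving the
    weighted moment sums with the fixed taper kernel, which is equivalent
    to calling :func:`weighted_pearson` at every time point.
    """
    if isinstance(window, int):
        raise TypeError("tapered window needs a WindowSpec with taper_std")
    if window.taper_std is None:
        raise ValueError("taper_std must be set for the tapered window")
    values = _as_values(pair)
    T = values.shape[0]
    L = window.length
    if L > T:
        raise ValueError("window longer than series")
    g = _taper_weights(L, window.taper_std)
    x = values[:, 0]
    y = values[:, 1]
    G = g.sum()
    conv = lambda v: np.convolve(v, g, mode="same")
    sx, sy = conv(x), conv(y)
    sxx, syy, sxy = conv(x * x), conv(y * y), conv(x * y)
    mx, my = sx / G, sy / G
    cov = sxy / G - mx * my
    vx = sxx / G - mx * mx
    vy = syy / G - my * my
    half = L // 2
    valid = np.zeros(T, dtype=bool)
    valid[half : T - half] = True
    with np.errstate(invalid="ignore", divide="ignore"):
        est = cov / np.sqrt(vx * vy)
    est = np.where(valid, np.clip(est, -1.0, 1.0), np.nan)
    if not np.isfinite(est[valid]).all():
        raise DegenerateSeriesError("degenerate weighted variance in a window")
    return TVCSeries(est, valid, method=f"TSW-{L}",
                     params={"length": L, "taper_std": window.taper_std})


# ---------------------------------------------------------------------------
# Spatial distance


def _sd_weight_bounds(values: np.ndarray, chunk_size: int) -> tuple[float, float]:
    """Smallest and largest inverse off-diagonal distance over the whole
    weight matrix (coincident pairs excluded; they later take the largest
    finite weight)."""
    from scipy.spatial.distance import cdist

    T = values.shape[0]
    d_min, d_max = np.inf, 0.0
    for start in range(0, T, chunk_size):
        idx = np.arange(start, min(start + chunk_size, T))
        D = cdist(values[idx], values)
        D[np.arange(idx.size), idx] = np.nan
        pos = D[D > 0]
        if pos.size:
            d_min = min(d_min, pos.min())
        d_max = max(d_max, np.nanmax(D))
    if not np.isfinite(d_min) or d_max <= 0 or d_min == d_max:
        raise DegenerateSeriesError("all pairwise distances coincide")
    return 1.0 / d_max, 1.0 / d_min


def _sd_weight_rows(values: np.ndarray, idx: np.ndarray,
                    w_lo: float, w_hi: float) -> np.ndarray:
    """Weight vectors for target time points ``idx`` (rows): w_u(t) =
    1/D(t, u) for u != t, min-max scaled to [0, 1] over the whole weight
    matrix (bounds precomputed), self weight forced to 1.  Coincident
    points (D = 0, u != t) take the largest finite weight, i.e. scale
    to 1."""
    from scipy.spatial.distance import cdist

    D = cdist(values[idx], values)  # (chunk, T)
    chunk = np.arange(idx.size)
    with np.errstate(divide="ignore"):
        W = 1.0 / D
    W[np.isinf(W)] = w_hi
    W = (W - w_lo) / (w_hi - w_lo)
    W[chunk, idx] = 1.0
    return W


def spatial_distance_tvc(series, mode: str = "bivariate",
                         distance: str = "euclidean",
                         chunk_size: int = 256):
    """Spatial-distance weighted correlation.

    ``series`` is a T x R matrix (R >= 2).  In bivariate mode (R = 2) the
    weights at each t come from the two series of the edge itself; in
    multivariate mode one shared weight set per t is computed from all R
    series and a :class:`TVCSeries` is returned per edge (i, j).

    Weights are the inverse Euclidean distances between amplitude vectors,
    min-max scaled to [0, 1] over the whole off-diagonal weight matrix,
    with the self weight forced to 1 afterwards.

    Every time point is valid, and the estimates are invariant (up to the
    same reordering) under any permutation of the time points.
    """
    if distance != "euclidean":
        raise ValueError("only the Euclidean distance is supported")
    values = np.asarray(series, dtype=float)
    if isinstance(series, BivariatePair):
        values = series.values
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("series must be T x R with R >= 2")
    T, R = values.shape
    if mode == "bivariate":
        if R != 2:
            raise ValueError("bivariate mode requires exactly two series")
        est = _sd_edge(values, values[:, 0], values[:, 1], chunk_size)
        return TVCSeries(est, np.ones(T, bool), method="SD",
                         params={"mode": mode, "distance": distance})
    if mode != "multivariate":
        raise ValueError("mode must be 'bivariate' or 'multivariate'")
    out = {}
    for i in range(R):
        for j in range(i + 1, R):
            est = _sd_edge(values, values[:, i], values[:, j], chunk_size)
            out[(i, j)] = TVCSeries(est, np.ones(T, bool), method="SD",
                                    params={"mode": mode, "edge": (i, j),
                                            "distance": distance})
    return out


def _sd_edge(weight_values: np.ndarray, x: np.ndarray, y: np.ndarray,
             chunk_size: int) -> np.ndarray:
    T = weight_values.shape[0]
    w_lo, w_hi = _sd_weight_bounds(weight_values, chunk_size)
    moments = np.column_stack([np.ones(T), x, y, x * x, y * y, x * y])
    est = np.empty(T)
    for start in range(0, T, chunk_size):
        idx = np.arange(start, min(start + chunk_size, T))
        W = _sd_weight_rows(weight_values, idx, w_lo, w_hi)
        S = W @ moments  # (chunk, 6): [wsum, sx, sy, sxx, syy, sxy]
        wsum = S[:, 0]
        mx, my = S[:, 1] / wsum, S[:, 2] / wsum
        vx = S[:, 3] / wsum - mx * mx
        vy = S[:, 4] / wsum - my * my
        cov = S[:, 5] / wsum - mx * my
        if np.any(vx <= 0) or np.any(vy <= 0):
            raise DegenerateSeriesError("zero weighted variance in SD weights")
        est[idx] = np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0)
    return est


# ---------------------------------------------------------------------------
# Jackknife / leave-n-out correlation


def jackknife_correlation(pair) -> TVCSeries:
    """Minus the leave-one-out Pearson correlation, assigned to the left-out t.

    The sign flip corrects the inversion inherent in leaving points out:
    a high-covariance point depresses the correlation of the remaining
    points, so the negated estimate tracks local covariance positively.
    Computed in O(T) via leave-one-out sufficient-statistic updates.
    """
    values = _as_values(pair)
    T = values.shape[0]
    if T < 3:
        raise ValueError("need T >= 3")
    x, y = values[:, 0], values[:, 1]
    n = T - 1
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    ex = (sx - x) / n
    ey = (sy - y) / n
    cov = (sxy - x * y) / n - ex * ey
    vx = (sxx - x * x) / n - ex * ex
    vy = (syy - y * y) / n - ey * ey
    if np.any(vx <= 0) or np.any(vy <= 0):
        raise DegenerateSeriesError("a leave-one-out subseries is constant")
    est = np.clip(-cov / np.sqrt(vx * vy), -1.0, 1.0)
    return TVCSeries(est, np.ones(T, bool), method="JC", params={})


def leave_n_out_correlation(pair, n: int) -> TVCSeries:
    """Minus the Pearson correlation excluding the n points centered at t.

    Near the series boundaries the block shifts inward so that exactly
    T - n points always remain; ``n = 1`` reproduces the jackknife.
    """
    values = _as_values(pair)
    T = values.shape[0]
    if not 1 <= n <= T - 2:
        raise ValueError("need 1 <= n <= T - 2")
    x, y = values[:, 0], values[:, 1]
    cum = lambda v: np.concatenate([[0.0], np.cumsum(v)])
    cx, cy = cum(x), cum(y)
    cxx, cyy, cxy = cum(x * x), cum(y * y), cum(x * y)
    t = np.arange(T)
    lo = np.clip(t - n // 2, 0, T - n)
    hi = lo + n
    m = T - n
    bx = cx[hi] - cx[lo]
    by = cy[hi] - cy[lo]
    ex = (cx[-1] - bx) / m
    ey = (cy[-1] - by) / m
    cov = (cxy[-1] - (cxy[hi] - cxy[lo])) / m - ex * ey
    vx = (cxx[-1] - (cxx[hi] - cxx[lo])) / m - ex * ex
    vy = (cyy[-1] - (cyy[hi] - cyy[lo])) / m - ey * ey
    if np.any(vx <= 0) or np.any(vy <= 0):
        raise DegenerateSeriesError("a leave-n-out subseries is constant")
    est = np.clip(-cov / np.sqrt(vx * vy), -1.0, 1.0)
    return TVCSeries(est, np.ones(T, bool), method=f"L{n}O", params={"n": n})


# ---------------------------------------------------------------------------
# Multiplication of temporal derivatives


def mtd(pair, smooth_window: int = 7) -> TVCSeries:
    """Product of first differences scaled by the derivatives' overall SDs.

    The raw coupling at t is ``df_x[t] * df_y[t] / (sd(df_x) * sd(df_y))``
    (t = 0 has no derivative and is invalid), smoothed with a centered
    boxcar mean of ``smooth_window`` points; edge points without a full
    smoothing window are invalid.  Output is product-scale, not bounded
    in [-1, 1], and is not Fisher-transformed downstream.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    values = _as_values(pair)
    T = values.shape[0]
    if T < smooth_window + 1:
        raise ValueError("series too short for the smoothing window")
    dx = np.diff(values[:, 0])
    dy = np.diff(values[:, 1])
    sdx, sdy = dx.std(), dy.std()
    if sdx == 0 or sdy == 0:
        raise DegenerateSeriesError("derivative has zero variance")
    raw = dx * dy / (sdx * sdy)  # aligned with t = 1 .. T-1
    half = smooth_window // 2
    if smooth_window == 1:
        smooth = raw
    else:
        kernel = np.full(smooth_window, 1.0 / smooth_window)
        smooth = np.convolve(raw, kernel, mode="valid")
    est = np.full(T, np.nan)
    valid = np.zeros(T, dtype=bool)
    start = 1 + half
    est[start : start + smooth.size] = smooth
    valid[start : start + smooth.size] = True
    return TVCSeries(est, valid, method=f"MTD-{smooth_window}",
                     params={"smooth_window": smooth_window},
                     correlation_scale=False)


# ---------------------------------------------------------------------------
# Post-processing


def fisher_transform(series: TVCSeries) -> TVCSeries:
    """Elementwise atanh over valid points (correlation-scale methods only)."""
    if not series.correlation_scale:
        raise ValueError(f"{series.method} is not on the correlation scale; "
                         "the Fisher transform does not apply")
    est = series.estimate.copy()
    v = series.valid
    est[v] = np.arctanh(np.clip(est[v], -_FISHER_CAP, _FISHER_CAP))
    return replace(series, estimate=est, correlation_scale=False,
                   params={**series.params, "fisher": True})


def standardize(series: TVCSeries, mask: np.ndarray | None = None) -> TVCSeries:
    """Zero mean, unit (population) SD over the valid points.

    If ``mask`` is given, the moments are computed over ``valid & mask``
    only (as when standardizing over a common mask before modelling).
    """
    sel = series.valid if mask is None else (series.valid & mask)
    vals = series.estimate[sel]
    if vals.size < 2:
        raise DegenerateSeriesError("too few valid points to standardize")
    sd = vals.std()
    if sd == 0:
        raise DegenerateSeriesError(f"{series.method} estimate is constant")
    est = series.estimate.copy()
    est[series.valid] = (series.estimate[series.valid] - vals.mean()) / sd
    return replace(series, estimate=est,
                   params={**series.params, "standardized": True})


def common_valid_mask(series_list) -> np.ndarray:
    """Logical AND of the validity masks of several TVC series."""
    series_list = list(series_list)
    if not series_list:
        raise ValueError("need at least one series")
    mask = np.ones(series_list[0].T, dtype=bool)
    for s in series_list:
        if s.T != mask.size:
            raise ValueError("series lengths differ")
        mask &= s.valid
    if not mask.any():
        raise ValueError("no time point is valid for every method")
    return mask
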