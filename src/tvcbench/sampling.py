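"""Gradient-based MCMC for the benchmark's Bayesian tracking model.

Implements the No-U-Turn Sampler (dynamic Hamiltonian Monte Carlo with
slice-based trajectory sampling and dual-averaging step-size adaptation)
for a differentiable log posterior.  The benchmark only ever samples a
three-parameter Gaussian linear regression, whose log posterior and
gradient reduce to sufficient statistics of (x, y), so each gradient
evaluation is O(1) regardless of the series length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["LinearModelPosterior", "nuts_sample"]

_DELTA_MAX = 1000.0  # divergence threshold on the Hamiltonian error


def _kinetic(r: np.ndarray) -> float:
    with np.errstate(over="ignore"):
        k = float(r @ r)
    return k if math.isfinite(k) else math.inf


@dataclass
class LinearModelPosterior:
    """Log posterior of ``y_i ~ N(a + b x_i, sigma)``.

    Priors: a, b ~ N(0, 1); sigma ~ HalfNormal(1).  Parameterized as
    theta = (a, b, log sigma) with the Jacobian term included, so the
    posterior is unconstrained and smooth.
    """

    n: int
    sx: float
    sy: float
    sxx: float
    syy: float
    sxy: float

    @classmethod
    def from_data(cls, x: np.ndarray, y: np.ndarray) -> "LinearModelPosterior":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D with equal length")
        if x.size < 10:
            raise ValueError("need at least 10 observations")
        return cls(
            n=x.size,
            sx=float(x.sum()),
            sy=float(y.sum()),
            sxx=float(x @ x),
            syy=float(y @ y),
            sxy=float(x @ y),
        )

    def _ssr(self, a: float, b: float) -> float:
        return (self.syy - 2 * a * self.sy - 2 * b * self.sxy
                + 2 * a * b * self.sx + a * a * self.n + b * b * self.sxx)

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        a, b, s = float(theta[0]), float(theta[1]), float(theta[2])
        if abs(s) > 300:  # overflow guard for wild trajectories / step search
            return -math.inf, np.array([0.0, 0.0, -math.copysign(1.0, s)])
        sig2 = math.exp(2 * s)
        ssr = self._ssr(a, b)
        lp = (-self.n * s - 0.5 * ssr / sig2          # likelihood (up to const)
              - 0.5 * (a * a + b * b)                 # N(0,1) priors on a, b
              - 0.5 * sig2 + s)                       # HalfNormal(1) + Jacobian
        d_ssr_da = -2 * self.sy + 2 * b * self.sx + 2 * a * self.n
        d_ssr_db = -2 * self.sxy + 2 * a * self.sx + 2 * b * self.sxx
        grad = np.array([
            -0.5 * d_ssr_da / sig2 - a,
            -0.5 * d_ssr_db / sig2 - b,
            -self.n + ssr / sig2 - sig2 + 1.0,
        ])
        return lp, grad

    def mle(self) -> tuple[float, float, float]:
        """Ordinary least-squares solution (a_hat, b_hat, sigma_hat)."""
        n = self.n
        vx = self.sxx / n - (self.sx / n) ** 2
        cov = self.sxy / n - self.sx * self.sy / n**2
        b = cov / vx
        a = self.sy / n - b * self.sx / n
        sig2 = self._ssr(a, b) / n
        return a, b, math.sqrt(sig2)


def _find_reasonable_epsilon(logp_grad, theta, rng) -> float:
    eps = 1.0
    lp, grad = logp_grad(theta)
    r = rng.standard_normal(theta.size)
    h0 = lp - 0.5 * _kinetic(r)
    theta1, r1, lp1, _ = _leapfrog(logp_grad, theta, r, grad, eps)
    h1 = lp1 - 0.5 * _kinetic(r1)
    if not math.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > math.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        theta1, r1, lp1, _ = _leapfrog(logp_grad, theta, r, grad, eps)
        h1 = lp1 - 0.5 * _kinetic(r1)
        if not math.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * math.log(0.5):
            break
    return eps


def _leapfrog(logp_grad, theta, r, grad, eps):
    r_half = r + 0.5 * eps * grad
    theta_new = theta + eps * r_half
    lp_new, grad_new = logp_grad(theta_new)
    r_new = r_half + 0.5 * eps * grad_new
    return theta_new, r_new, lp_new, grad_new


def _build_tree(logp_grad, theta, r, grad, logu, v, j, eps, h0, rng):
    """Recursive NUTS tree doubling; returns the standard tuple of
    (left/right states, proposal, n_accept_slice, continue_flag,
    accept_stat_sum, accept_stat_count, n_divergent)."""
    if j == 0:
        theta1, r1, lp1, grad1 = _leapfrog(logp_grad, theta, r, grad, v * eps)
        h1 = lp1 - 0.5 * _kinetic(r1)
        if not math.isfinite(h1):
            h1 = -np.inf
        n1 = 1 if logu <= h1 else 0
        diverged = logu >= h1 + _DELTA_MAX
        alpha = min(1.0, math.exp(min(0.0, h1 - h0)))
        return (theta1, r1, grad1, theta1, r1, grad1, theta1, lp1, grad1,
                n1, not diverged, alpha, 1, int(diverged))
    (tm, rm, gm, tp, rp, gp, tprop, lpprop, gprop,
     n1, s1, a1, na1, ndiv1) = _build_tree(
        logp_grad, theta, r, grad, logu, v, j - 1, eps, h0, rng)
    ndiv2 = 0
    if s1:
        if v == -1:
            (tm, rm, gm, _, _, _, tprop2, lpprop2, gprop2,
             n2, s2, a2, na2, ndiv2) = _build_tree(
                logp_grad, tm, rm, gm, logu, v, j - 1, eps, h0, rng)
        else:
            (_, _, _, tp, rp, gp, tprop2, lpprop2, gprop2,
             n2, s2, a2, na2, ndiv2) = _build_tree(
                logp_grad, tp, rp, gp, logu, v, j - 1, eps, h0, rng)
        if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
            tprop, lpprop, gprop = tprop2, lpprop2, gprop2
        dtheta = tp - tm
        s1 = s2 and float(dtheta @ rm) >= 0 and float(dtheta @ rp) >= 0
        n1 += n2
        a1 += a2
        na1 += na2
    return (tm, rm, gm, tp, rp, gp, tprop, lpprop, gprop,
            n1, s1, a1, na1, ndiv1 + ndiv2)


def nuts_sample(
    logp_grad,
    theta0: np.ndarray,
    draws: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
):
    """Run one NUTS chain; the step size adapts during the first ``warmup``
    iterations (dual averaging) and is then frozen.

    Returns (samples, stats): samples has shape (draws, dim) and includes
    the warmup iterations at the front; stats reports divergences (post
    warmup), the adapted step size and the mean acceptance statistic.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    lp, grad = logp_grad(theta)
    dim = theta.size

    eps = _find_reasonable_epsilon(logp_grad, theta, rng)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    samples = np.empty((draws, dim))
    divergences = 0
    accept_sum = 0.0

    for m in range(draws):
        r0 = rng.standard_normal(dim)
        h0 = lp - 0.5 * _kinetic(r0)
        logu = h0 + math.log(rng.random())
        tm = tp = theta
        rm = rp = r0
        gm = gp = grad
        j, n, s = 0, 1, True
        alpha_sum, n_alpha = 0.0, 1
        while s and j < max_treedepth:
            v = -1 if rng.random() < 0.5 else 1
            if v == -1:
                (tm, rm, gm, _, _, _, tprop, lpprop, gprop,
                 n1, s1, a1, na1, ndiv) = _build_tree(
                    logp_grad, tm, rm, gm, logu, v, j, eps, h0, rng)
            else:
                (_, _, _, tp, rp, gp, tprop, lpprop, gprop,
                 n1, s1, a1, na1, ndiv) = _build_tree(
                    logp_grad, tp, rp, gp, logu, v, j, eps, h0, rng)
            if m >= warmup:
                divergences += ndiv
            if s1 and n1 > 0 and rng.random() < min(1.0, n1 / n):
                theta, lp, grad = tprop, lpprop, gprop
            n += n1
            dtheta = tp - tm
            s = s1 and float(dtheta @ rm) >= 0 and float(dtheta @ rp) >= 0
            alpha_sum, n_alpha = a1, na1
            j += 1
        if m < warmup:
            frac = 1.0 / (m + 1 + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - alpha_sum / n_alpha)
            log_eps = mu - math.sqrt(m + 1) / gamma * h_bar
            w = (m + 1) ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = math.exp(log_eps)
        elif m == warmup:
            eps = math.exp(log_eps_bar)
        else:
            accept_sum += alpha_sum / n_alpha
        samples[m] = theta

    n_kept = max(draws - warmup - 1, 1)
    stats = {
        "step_size": eps,
        "divergences": divergences,
        "mean_accept": accept_sum / n_kept,
    }
    return samples, stats
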