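"""Estimator checks: oracles, symmetries and post-processing invariants."""

import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

import tvcbench
from tvcbench import methods
from tvcbench.methods import (
    DegenerateSeriesError,
    WindowSpec,
    common_valid_mask,
    fisher_transform,
    jackknife_correlation,
    leave_n_out_correlation,
    mtd,
    sliding_window,
    spatial_distance_tvc,
    standardize,
    tapered_sliding_window,
    weighted_pearson,
)
from tvcbench.simgen import CovarianceTrack, simulate_with_track


class TestWeightedPearson:
    def test_uniform_weights_reduce_to_pearson(self, rng):
        x, y = rng.standard_normal((2, 50))
        assert weighted_pearson(x, y, np.ones(50)) == pytest.approx(
            pearsonr(x, y).statistic)

    def test_zero_weights_exclude_points(self, rng):
        x, y = rng.standard_normal((2, 50))
        w = np.zeros(50)
        w[10:25] = 1.0
        assert weighted_pearson(x, y, w) == pytest.approx(
            pearsonr(x[10:25], y[10:25]).statistic)

    def test_restricted_perfectly_linear_triple(self):
        # dropping the 4th point leaves (1,2,3) vs (1,2,3): exactly linear
        assert weighted_pearson([1, 2, 3, 4], [1, 2, 3, 5],
                                [1, 1, 1, 0]) == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            weighted_pearson([1, 1, 1], [1, 2, 3], [1, 1, 1])
        with pytest.raises(DegenerateSeriesError):
            weighted_pearson([1, 2, 3], [1, 2, 3], [1, 0, 0])
        with pytest.raises(ValueError):
            weighted_pearson([1, 2, 3], [1, 2, 3], [1, -1, 1])


class TestSlidingWindow:
    def test_valid_count_and_edges(self, sim1_small):
        s = sliding_window(sim1_small.pair, WindowSpec(29))
        assert s.valid.sum() == 2000 - 28
        assert not s.valid[:14].any() and not s.valid[-14:].any()

    def test_matches_per_window_pearson(self, rng):
        v = rng.standard_normal((100, 2))
        s = sliding_window(v, WindowSpec(15))
        for t in range(7, 93):
            ref = pearsonr(v[t - 7 : t + 8, 0], v[t - 7 : t + 8, 1]).statistic
            assert s.estimate[t] == pytest.approx(ref, abs=1e-10)

    def test_identical_series_give_unit_correlation(self, rng):
        x = rng.standard_normal(60)
        s = sliding_window(np.column_stack([x, x]), WindowSpec(9))
        np.testing.assert_allclose(s.estimate[s.valid], 1.0)

    def test_full_length_window_is_global_pearson(self, rng):
        v = rng.standard_normal((31, 2))
        s = sliding_window(v, WindowSpec(31))
        assert s.valid.sum() == 1
        assert s.estimate[15] == pytest.approx(
            pearsonr(v[:, 0], v[:, 1]).statistic)

    def test_window_validation(self, rng):
        v = rng.standard_normal((20, 2))
        with pytest.raises(ValueError):
            sliding_window(v, WindowSpec(29))
        with pytest.raises(ValueError):
            WindowSpec(14)  # even length has no center point


class TestTaperedSlidingWindow:
    def test_matches_weighted_pearson_oracle(self, rng):
        v = rng.standard_normal((80, 2))
        spec = WindowSpec(15, taper_std=3.0)
        s = tapered_sliding_window(v, spec)
        k = np.arange(15) - 7
        g = np.exp(-0.5 * (k / 3.0) ** 2)
        for t in range(7, 73):
            ref = weighted_pearson(v[t - 7 : t + 8, 0], v[t - 7 : t + 8, 1], g)
            assert s.estimate[t] == pytest.approx(ref, abs=1e-10)

    def test_flat_taper_limit_recovers_sliding_window(self, sim1_small):
        sw = sliding_window(sim1_small.pair, WindowSpec(15))
        tsw = tapered_sliding_window(sim1_small.pair,
                                     WindowSpec(15, taper_std=1e4))
        diff = np.abs(sw.estimate[sw.valid] - tsw.estimate[tsw.valid])
        assert diff.max() < 1e-6

    def test_identical_series_give_unit_correlation(self, rng):
        x = rng.standard_normal(60)
        s = tapered_sliding_window(np.column_stack([x, x]),
                                   WindowSpec(9, taper_std=2.0))
        np.testing.assert_allclose(s.estimate[s.valid], 1.0)


def _sd_bruteforce(v):
    """Literal evaluation of the spatial-distance estimator: inverse
    Euclidean distances, min-max scaled over the whole off-diagonal weight
    matrix, self weight 1, then a weighted Pearson correlation per t."""
    T = v.shape[0]
    D = np.sqrt(((v[:, None, :] - v[None, :, :]) ** 2).sum(-1))
    W = np.zeros((T, T))
    off = ~np.eye(T, dtype=bool)
    W[off] = 1.0 / D[off]
    lo, hi = W[off].min(), W[off].max()
    W[off] = (W[off] - lo) / (hi - lo)
    np.fill_diagonal(W, 1.0)
    return np.array([weighted_pearson(v[:, 0], v[:, 1], W[t]) for t in range(T)])


class TestSpatialDistance:
    def test_matches_bruteforce_oracle(self, rng):
        v = rng.standard_normal((40, 2))
        s = spatial_distance_tvc(v)
        np.testing.assert_allclose(s.estimate, _sd_bruteforce(v), atol=1e-10)

    def test_three_point_toy_case(self):
        v = np.array([[0.0, 0.0], [1.0, 0.5], [0.2, -1.0]])
        s = spatial_distance_tvc(v)
        np.testing.assert_allclose(s.estimate, _sd_bruteforce(v), atol=1e-12)
        assert s.valid.all()

    def test_permutation_invariance(self, rng):
        v = rng.standard_normal((60, 2))
        perm = rng.permutation(60)
        direct = spatial_distance_tvc(v).estimate
        shuffled = spatial_distance_tvc(v[perm]).estimate
        np.testing.assert_allclose(shuffled, direct[perm], atol=1e-10)

    def test_multivariate_mode_shares_weights_per_edge(self, rng):
        v = rng.standard_normal((30, 3))
        out = spatial_distance_tvc(v, mode="multivariate")
        assert set(out) == {(0, 1), (0, 2), (1, 2)}
        for s in out.values():
            assert s.valid.all()
            assert np.abs(s.estimate).max() <= 1

    def test_bivariate_mode_requires_two_series(self, rng):
        with pytest.raises(ValueError):
            spatial_distance_tvc(rng.standard_normal((30, 3)), mode="bivariate")


def _jc_bruteforce(v):
    T = v.shape[0]
    out = np.empty(T)
    for t in range(T):
        keep = np.ones(T, dtype=bool)
        keep[t] = False
        out[t] = -pearsonr(v[keep, 0], v[keep, 1]).statistic
    return out


class TestJackknife:
    @pytest.mark.parametrize("T", [10, 57, 200])
    def test_fast_path_equals_bruteforce(self, T):
        v = np.random.default_rng(T).standard_normal((T, 2))
        fast = jackknife_correlation(v).estimate
        np.testing.assert_allclose(fast, _jc_bruteforce(v), atol=1e-10)

    def test_perfectly_linear_triple_gives_minus_one(self):
        v = np.column_stack([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0]])
        np.testing.assert_allclose(jackknife_correlation(v).estimate, -1.0)

    def test_estimate_ignores_own_value(self, rng):
        v = rng.standard_normal((50, 2))
        base = jackknife_correlation(v).estimate
        v2 = v.copy()
        v2[20] = [100.0, -100.0]
        assert jackknife_correlation(v2).estimate[20] == pytest.approx(
            base[20], abs=1e-12)

    def test_permutation_invariance(self, rng):
        v = rng.standard_normal((60, 2))
        perm = rng.permutation(60)
        direct = jackknife_correlation(v).estimate
        np.testing.assert_allclose(jackknife_correlation(v[perm]).estimate,
                                   direct[perm], atol=1e-12)

    def test_variance_compression_grows_with_length(self):
        # same generating covariance, longer series -> tighter JC spread
        sds = {}
        for T in (400, 4000):
            track = CovarianceTrack(np.full(T, 0.5))
            ds = simulate_with_track(track, seed=99)
            sds[T] = jackknife_correlation(ds.pair.values).estimate.std()
        assert sds[4000] < sds[400]


def _leave_n_out_bruteforce(v, n):
    T = v.shape[0]
    out = np.empty(T)
    for t in range(T):
        keep = np.ones(T, dtype=bool)
        lo = min(max(0, t - n // 2), T - n)
        keep[lo : lo + n] = False
        out[t] = -pearsonr(v[keep, 0], v[keep, 1]).statistic
    return out


class TestLeaveNOut:
    def test_n1_reproduces_jackknife_exactly(self, rng):
        v = rng.standard_normal((80, 2))
        np.testing.assert_allclose(leave_n_out_correlation(v, 1).estimate,
                                   jackknife_correlation(v).estimate,
                                   atol=1e-12)

    @pytest.mark.parametrize("n", [3, 10, 33])
    def test_matches_bruteforce(self, n, rng):
        v = rng.standard_normal((70, 2))
        np.testing.assert_allclose(leave_n_out_correlation(v, n).estimate,
                                   _leave_n_out_bruteforce(v, n), atol=1e-10)

    def test_two_remaining_points_are_perfectly_correlated(self, rng):
        v = rng.standard_normal((30, 2))
        est = leave_n_out_correlation(v, 28).estimate
        np.testing.assert_allclose(np.abs(est), 1.0)

    def test_symmetry_with_window_length_n(self):
        """Stepped-covariance demonstration: a leave-n-out series (already
        sign-corrected) ranks time points like the window-length-n series."""
        steps = np.repeat([0.8, 0.6, 0.4, 0.2, 0.0], 2000)
        ds = simulate_with_track(CovarianceTrack(steps), seed=21)
        for n in (101, 1001, 4999):
            lno = leave_n_out_correlation(ds.pair.values, n)
            win = sliding_window(ds.pair.values, WindowSpec(n))
            mask = lno.valid & win.valid
            rho = spearmanr(lno.estimate[mask], win.estimate[mask]).statistic
            assert rho > 0.95


class TestMTD:
    def test_identical_derivatives_average_to_one(self, rng):
        x = np.cumsum(rng.standard_normal(2000))
        v = np.column_stack([x, x])
        s = mtd(v, smooth_window=1)
        est = s.estimate[s.valid]
        assert est.min() >= 0  # squared derivative over its variance
        assert est.mean() == pytest.approx(1.0, abs=0.01)

    def test_linear_input_has_zero_derivative_variance(self):
        t = np.arange(100.0)
        with pytest.raises(DegenerateSeriesError):
            mtd(np.column_stack([2 * t, 3 * t]))

    def test_unit_smoothing_is_identity(self, rng):
        v = rng.standard_normal((50, 2))
        raw = mtd(v, smooth_window=1)
        dx, dy = np.diff(v[:, 0]), np.diff(v[:, 1])
        expected = dx * dy / (dx.std() * dy.std())
        np.testing.assert_allclose(raw.estimate[1:], expected, atol=1e-12)
        assert not raw.valid[0]

    def test_smoothing_edge_validity(self, rng):
        v = rng.standard_normal((50, 2))
        s = mtd(v, smooth_window=7)
        assert not s.valid[:4].any() and not s.valid[-3:].any()
        assert s.valid[4:-3].all()


class TestPostProcessing:
    def test_fisher_known_values_and_monotonicity(self):
        s = methods.TVCSeries(np.array([0.0, 0.5, 0.9]), np.ones(3, bool), "JC")
        z = fisher_transform(s)
        np.testing.assert_allclose(z.estimate,
                                   [0.0, np.arctanh(0.5), np.arctanh(0.9)])
        assert np.all(np.diff(z.estimate) > 0)

    def test_fisher_rejects_product_scale_series(self, rng):
        s = mtd(rng.standard_normal((50, 2)))
        with pytest.raises(ValueError, match="correlation scale"):
            fisher_transform(s)

    def test_fisher_handles_exact_unit_correlation(self, rng):
        x = rng.standard_normal(60)
        s = sliding_window(np.column_stack([x, x]), WindowSpec(9))
        z = fisher_transform(s)
        assert np.isfinite(z.estimate[z.valid]).all()

    def test_standardize_moments_and_idempotence(self, sim1_small):
        s = jackknife_correlation(sim1_small.pair.values)
        z = standardize(s)
        assert z.estimate[z.valid].mean() == pytest.approx(0.0, abs=1e-12)
        assert z.estimate[z.valid].std() == pytest.approx(1.0)
        zz = standardize(z)
        np.testing.assert_allclose(zz.estimate[z.valid],
                                   z.estimate[z.valid], atol=1e-10)

    def test_standardize_rejects_constant_series(self):
        s = methods.TVCSeries(np.ones(10), np.ones(10, bool), "X")
        with pytest.raises(DegenerateSeriesError):
            standardize(s)

    def test_common_mask_is_intersection(self):
        ds = tvcbench.simulate_sim1(T=10_000, seed=1)
        sw = sliding_window(ds.pair, WindowSpec(29))
        jc = jackknife_correlation(ds.pair.values)
        mask = common_valid_mask([sw, jc])
        assert mask.sum() == 9_972

    def test_raw_correlation_estimates_bounded(self, sim1_small):
        for s in (sliding_window(sim1_small.pair, WindowSpec(15)),
                  tapered_sliding_window(sim1_small.pair,
                                         WindowSpec(15, taper_std=10.0)),
                  jackknife_correlation(sim1_small.pair.values)):
            est = s.estimate[s.valid]
            assert est.min() >= -1 and est.max() <= 1
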