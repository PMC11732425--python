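"""Geometry and estimator contracts of the sliding-window Poincare analysis."""

import numpy as np
import pytest
from sklearn.covariance import LedoitWolf

from autonomic import (
    CovMethod,
    IbiSeries,
    LaggedPairs,
    compute_ccd,
    descriptor_series,
    estimate_covariance,
    sd_approximate,
    sd_from_covariance,
    window_pairs,
)
from conftest import alternating_ibi, constant_ibi


class TestWindowPairs:
    def test_constant_series_count_and_values(self):
        ibi = constant_ibi(1.0, 60)
        pairs = window_pairs(ibi, t=30.0, T=15.0)
        assert 13 <= pairs.n <= 16
        assert np.all(pairs.x == 1.0) and np.all(pairs.y == 1.0)

    def test_before_first_beat_is_empty(self):
        pairs = window_pairs(constant_ibi(), t=-5.0, T=15.0)
        assert pairs.n == 0

    def test_matches_brute_force_enumeration(self, rng):
        vals = rng.uniform(0.6, 1.2, 200)
        ibi = IbiSeries(t=np.cumsum(vals), ibi=vals)
        for t in rng.uniform(0, ibi.t[-1] + 5, 25):
            T = rng.uniform(3, 30)
            fast = window_pairs(ibi, t, T)
            # O(n^2)-style oracle: scan every candidate pair explicitly
            xs, ys = [], []
            for i in range(ibi.n - 1):
                if t - T <= ibi.t[i] <= t and t - T <= ibi.t[i + 1] <= t:
                    xs.append(ibi.ibi[i])
                    ys.append(ibi.ibi[i + 1])
            np.testing.assert_array_equal(fast.x, xs)
            np.testing.assert_array_equal(fast.y, ys)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            window_pairs(constant_ibi(), t=10.0, T=0.0)


class TestComputeCcd:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            (np.ones(10), np.ones(10), np.sqrt(2.0)),
            (np.full(7, 0.8), np.full(7, 0.8), 0.8 * np.sqrt(2.0)),
            ([0.8, 1.0], [1.0, 1.4], 1.5),  # means 0.9 and 1.2: a 3-4-5 triangle
        ],
    )
    def test_closed_forms(self, x, y, expected):
        assert compute_ccd(LaggedPairs(x=x, y=y)) == pytest.approx(expected, rel=1e-12)

    def test_empty_window_is_missing(self):
        assert np.isnan(compute_ccd(LaggedPairs(x=[], y=[])))


class TestEstimateCovariance:
    def test_exact_is_sample_covariance(self, rng):
        x, y = rng.normal(size=(2, 50))
        cov = estimate_covariance(LaggedPairs(x=x, y=y), "exact")
        np.testing.assert_allclose(cov, np.cov(np.vstack((x, y)), ddof=1), rtol=1e-12)

    def test_ledoit_wolf_matches_sklearn(self, rng):
        """Dual route: the in-package analytic shrinkage equals sklearn's."""
        X = rng.multivariate_normal([0.9, 0.9], [[0.01, 0.006], [0.006, 0.012]], size=40)
        ours = estimate_covariance(LaggedPairs(x=X[:, 0], y=X[:, 1]), "robust")
        ref = LedoitWolf().fit(X).covariance_
        np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_shrinkage_vanishes_at_large_n(self, rng):
        X = rng.multivariate_normal([0, 0], [[1.0, 0.3], [0.3, 0.8]], size=10_000)
        pairs = LaggedPairs(x=X[:, 0], y=X[:, 1])
        robust = estimate_covariance(pairs, "robust")
        exact = estimate_covariance(pairs, "exact")
        dist = np.linalg.norm(robust - exact) / np.linalg.norm(exact)
        assert dist < 0.02

    def test_mcd_withstands_gross_outliers(self, rng):
        clean = rng.multivariate_normal([0.9, 0.9], [[0.01, 0.005], [0.005, 0.01]], size=100)
        sigma = 0.1
        dirty = clean.copy()
        dirty[:2] += 10 * sigma  # two gross outliers
        clean_cov = np.cov(clean.T, ddof=1)
        pairs = LaggedPairs(x=dirty[:, 0], y=dirty[:, 1])
        p95 = estimate_covariance(pairs, CovMethod("p95", seed=0))
        exact = estimate_covariance(pairs, "exact")
        assert np.linalg.norm(p95 - clean_cov) / np.linalg.norm(clean_cov) < 0.25
        assert np.trace(exact) / np.trace(clean_cov) > 2.0

    def test_mcd_small_sample_enumeration_is_exact(self, rng):
        from itertools import combinations

        from autonomic.poincare import _mcd_cov

        X = rng.normal(size=(18, 2))
        ours = _mcd_cov(X, 0.05, seed=0)
        h = int(round(0.95 * 18))
        best, best_det = None, np.inf
        for keep in combinations(range(18), h):
            cov = np.cov(X[list(keep)].T, ddof=1)
            det = np.linalg.det(cov)
            if det < best_det:
                best_det, best = det, cov
        np.testing.assert_allclose(ours, best, rtol=1e-12)

    def test_collinear_pairs_allowed(self):
        x = np.linspace(0.8, 1.0, 30)
        cov = estimate_covariance(LaggedPairs(x=x, y=x), "exact")
        evals = np.linalg.eigvalsh(cov)
        assert evals[0] == pytest.approx(0.0, abs=1e-15)

    def test_too_few_pairs_gives_missing(self):
        assert estimate_covariance(LaggedPairs(x=[1, 2], y=[2, 1]), "exact") is None
        assert estimate_covariance(LaggedPairs(x=[1] * 4, y=[1] * 4), "p95") is None


class TestSdFromCovariance:
    def test_isotropic(self):
        sd1, sd2 = sd_from_covariance(np.diag([0.04, 0.04]))
        assert sd1 == pytest.approx(0.2) and sd2 == pytest.approx(0.2)

    def test_alternating_orientation_assignment(self):
        d = 0.05
        cov = np.array([[d**2, -(d**2)], [-(d**2), d**2]])
        sd1, sd2 = sd_from_covariance(cov)
        # anti-correlated cloud: all dispersion is across the identity line
        assert sd1 == pytest.approx(d * np.sqrt(2), rel=1e-12)
        assert sd2 == pytest.approx(0.0, abs=1e-12)

    def test_identity_line_dispersion_is_sd2(self):
        s = 0.03
        cov = np.array([[s**2, s**2], [s**2, s**2]])
        sd1, sd2 = sd_from_covariance(cov)
        assert sd2 == pytest.approx(s * np.sqrt(2), rel=1e-12)
        assert sd1 == pytest.approx(0.0, abs=1e-12)

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            sd_from_covariance(np.array([[-1e-3, 0.0], [0.0, 1.0]]))

    def test_ar1_analytic_limit(self, rng):
        """Stationary AR(1): SD1 -> sqrt(g0-g1), SD2 -> sqrt(g0+g1)."""
        phi, sd_eps, n = 0.6, 0.02, 5000
        eps = rng.normal(0, sd_eps, n)
        x = np.empty(n)
        x[0] = eps[0] / np.sqrt(1 - phi**2)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        g0 = sd_eps**2 / (1 - phi**2)
        g1 = phi * g0
        pairs = LaggedPairs(x=x[:-1], y=x[1:])
        sd1, sd2 = sd_from_covariance(estimate_covariance(pairs, "exact"))
        assert sd1 == pytest.approx(np.sqrt(g0 - g1), rel=0.03)
        assert sd2 == pytest.approx(np.sqrt(g0 + g1), rel=0.03)


class TestSdApproximate:
    def test_constant_window(self):
        sd1, sd2 = sd_approximate(np.full(50, 0.8))
        assert sd1 == pytest.approx(0.0, abs=1e-12)
        assert sd2 == pytest.approx(0.0, abs=1e-12)

    def test_alternating_matches_eigen_route(self):
        ibi = alternating_ibi(m=0.9, d=0.05, n=500)
        sd1, sd2 = sd_approximate(ibi.ibi)
        # sample-convention estimates converge to the population closed form
        assert sd1 == pytest.approx(0.05 * np.sqrt(2), rel=0.01)
        assert sd2 == pytest.approx(0.0, abs=0.01)
        pairs = LaggedPairs(x=ibi.ibi[:-1], y=ibi.ibi[1:])
        e1, e2 = sd_from_covariance(estimate_covariance(pairs, "exact"))
        assert sd1 == pytest.approx(e1, rel=0.01)

    def test_white_noise_limit(self, rng):
        sigma = 0.03
        v = 0.9 + rng.normal(0, sigma, 5000)
        sd1, sd2 = sd_approximate(v)
        assert sd1 == pytest.approx(sigma, rel=0.05)
        assert sd2 == pytest.approx(sigma, rel=0.05)

    def test_too_few_is_missing(self):
        sd1, sd2 = sd_approximate([0.9, 1.0])
        assert np.isnan(sd1) and np.isnan(sd2)


class TestDescriptorSeries:
    def test_constant_ibis(self):
        desc = descriptor_series(constant_ibi(1.0, 60), T=15.0, method="exact")
        full = desc.t >= desc.t[0] + 15.0
        np.testing.assert_allclose(desc.ccd[full], np.sqrt(2.0), rtol=1e-12)
        np.testing.assert_allclose(desc.sd1[full], 0.0, atol=1e-12)
        np.testing.assert_allclose(desc.sd2[full], 0.0, atol=1e-12)

    def test_exact_equals_brute_force_oracle(self, rng):
        vals = 0.9 + 0.05 * np.sin(0.7 * np.arange(600)) + rng.normal(0, 0.01, 600)
        ibi = IbiSeries(t=np.cumsum(vals), ibi=vals)
        desc = descriptor_series(ibi, T=15.0, method="exact")
        for i in rng.choice(ibi.n, size=60, replace=False):
            te = ibi.t[i]
            mask = (ibi.t >= te - 15.0) & (ibi.t <= te)
            idx = np.flatnonzero(mask)
            idx = idx[idx + 1 <= idx[-1]]  # pairs fully inside
            x, y = vals[idx], vals[idx + 1]
            if x.size < 3:
                assert np.isnan(desc.sd1[i])
                continue
            assert desc.ccd[i] == pytest.approx(np.hypot(x.mean(), y.mean()), abs=1e-10)
            ev, evec = np.linalg.eigh(np.cov(np.vstack((x, y)), ddof=1))
            along = np.abs(evec.T @ (np.ones(2) / np.sqrt(2)))
            sd2 = np.sqrt(max(ev[np.argmax(along)], 0))
            sd1 = np.sqrt(max(ev[1 - np.argmax(along)], 0))
            assert desc.sd1[i] == pytest.approx(sd1, abs=1e-10)
            assert desc.sd2[i] == pytest.approx(sd2, abs=1e-10)

    def test_per_beat_grid_length(self, stationary_ibi):
        desc = descriptor_series(stationary_ibi, T=15.0, method="approximate")
        assert desc.n == stationary_ibi.n

    def test_step_change_moves_ccd_not_sd1(self, cold_pressor_ibi):
        ibi, cfg = cold_pressor_ibi
        desc = descriptor_series(ibi, T=15.0, method="exact")
        tt = cfg.transition_time
        pre = (desc.t > tt - 60) & (desc.t <= tt)
        post = desc.t > tt + 20  # past the window transient
        assert np.nanmean(desc.ccd[post]) < np.nanmean(desc.ccd[pre]) * 0.9

    def test_sd2_geq_sd1_on_hrv_like_input(self, stationary_ibi):
        """Positively lag-correlated series: long-term dispersion dominates
        and the orientation assignment never swaps the axes."""
        for method in ("exact", "robust", "p95", "approximate"):
            desc = descriptor_series(stationary_ibi, T=15.0, method=method)
            ok = np.isfinite(desc.sd1) & np.isfinite(desc.sd2)
            frac = np.mean(desc.sd2[ok] >= desc.sd1[ok])
            assert frac > 0.95, method

    def test_exact_vs_approximate_agreement(self):
        """The eigen route and the closed forms are algebraically equivalent
        up to finite-window edge terms."""
        rng = np.random.default_rng(7)
        rel_errs = []
        for _ in range(10):
            vals = 0.9 + 0.04 * np.sin(1.4 * np.arange(500)) + rng.normal(0, 0.01, 500)
            ibi = IbiSeries(t=np.cumsum(vals), ibi=vals)
            pairs = LaggedPairs(x=vals[:-1], y=vals[1:])
            e1, e2 = sd_from_covariance(estimate_covariance(pairs, "exact"))
            a1, a2 = sd_approximate(vals)
            rel_errs += [abs(e1 - a1) / e1, abs(e2 - a2) / e2]
        assert np.median(rel_errs) < 0.05

    def test_p95_breakdown_resistance(self, rng):
        """Replacing 5% of pairs with far-away values barely moves p95."""
        X = rng.multivariate_normal([0.9, 0.9], [[0.01, 0.006], [0.006, 0.01]], size=200)
        clean = estimate_covariance(LaggedPairs(x=X[:, 0], y=X[:, 1]), CovMethod("p95"))
        dirty = X.copy()
        dirty[:10] = [5.0, 5.0]  # 5% arbitrary values far from the bulk
        contaminated = estimate_covariance(
            LaggedPairs(x=dirty[:, 0], y=dirty[:, 1]), CovMethod("p95")
        )
        assert np.linalg.norm(contaminated - clean) / np.linalg.norm(clean) < 0.25

    def test_duration_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="longer than"):
            descriptor_series(constant_ibi(1.0, 10), T=15.0)
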