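"""Statistical machinery: each test checks against an independent oracle
(exhaustive enumeration, closed forms, or scipy's reference implementation)."""

import numpy as np
import pytest
from scipy import stats

from autonomic import (
    binomial_posthoc,
    effect_magnitude,
    friedman,
    robustness_experiment,
    spearman_t,
    wilcoxon_signed_rank,
    zscore_per_trial,
)
from autonomic.preprocess import IbiSeries
from autonomic.synth import cold_pressor, ipfm_beats
from autonomic.preprocess import build_ibi


class TestZscorePerTrial:
    def test_three_point_example(self):
        np.testing.assert_allclose(zscore_per_trial([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_moments_of_random_input(self, rng):
        z = zscore_per_trial(rng.normal(3.0, 2.5, 400))
        assert abs(np.mean(z)) < 1e-12
        assert abs(np.std(z, ddof=1) - 1.0) < 1e-12

    def test_nan_samples_pass_through(self, rng):
        v = rng.normal(size=50)
        v[7] = np.nan
        z = zscore_per_trial(v)
        assert np.isnan(z[7]) and np.isfinite(np.delete(z, 7)).all()

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            zscore_per_trial(np.full(10, 3.0))


class TestWilcoxonSignedRank:
    def test_uniformly_positive_differences_exact_p(self):
        pre = np.arange(10.0)
        res = wilcoxon_signed_rank(pre, pre + 1.0)
        assert res.w == 55.0
        assert res.p == pytest.approx(2.0 / 1024.0, rel=1e-12)

    def test_exact_p_matches_scipy_enumeration(self, rng):
        # untied data so scipy's exact method is directly comparable
        for _ in range(5):
            d = rng.normal(0.3, 1.0, 11)
            d = d[d != 0]
            pre = rng.normal(size=d.size)
            res = wilcoxon_signed_rank(pre, pre + d)
            ref = stats.wilcoxon(pre + d, pre, alternative="two-sided", method="exact")
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_normal_approximation_matches_scipy(self, rng):
        pre = rng.normal(size=40)
        post = pre + rng.normal(0.2, 1.0, 40)
        res = wilcoxon_signed_rank(pre, post)
        ref = stats.wilcoxon(post, pre, alternative="two-sided", method="approx",
                             correction=False)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)
        assert abs(res.z) == pytest.approx(abs(ref.zstatistic), rel=1e-9)

    def test_antisymmetric_differences_give_zero_z(self):
        pre = np.zeros(10)
        post = np.array([+1, -1, +2, -2, +3, -3, +4, -4, +5, -5], dtype=float)
        res = wilcoxon_signed_rank(pre, post)
        assert res.z == pytest.approx(0.0, abs=1e-12)

    def test_identical_pairs_rejected(self):
        v = np.arange(8.0)
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(v, v)

    def test_bonferroni_alpha_reported(self):
        pre = np.arange(10.0)
        res = wilcoxon_signed_rank(pre, pre + 1.0, n_comparisons=4)
        assert res.alpha == pytest.approx(0.0125)
        assert res.significant


class TestFriedman:
    def test_identical_columns_are_null(self):
        m = np.tile(np.arange(8.0)[:, None], (1, 4))
        stat, p = friedman(m)
        assert stat == 0.0 and p == 1.0

    def test_strictly_ordered_rows_closed_form(self):
        # every row ranks the 5 conditions identically: stat = 12n/(k(k+1)) *
        # sum (Rbar - (k+1)/2)^2 = 40 for n=10, k=5
        m = np.arange(5.0)[None, :] + np.zeros((10, 1))
        m = m + 0.001 * np.arange(10)[:, None]  # distinct rows, same order
        stat, p = friedman(m)
        assert stat == pytest.approx(40.0, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(40.0, 4), rel=1e-12)

    def test_matches_scipy_on_random_data(self, rng):
        m = rng.normal(size=(12, 4))
        stat, p = friedman(m)
        ref = stats.friedmanchisquare(*m.T)
        assert stat == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_permuting_conditions_preserves_null_behaviour(self, rng):
        """Exchangeability smoke test: under the null the statistic's
        distribution is invariant to relabelling the conditions."""
        m = rng.normal(size=(10, 4))
        base, _ = friedman(m)
        stats_perm = []
        for _ in range(200):
            perm = rng.permutation(4)
            stats_perm.append(friedman(m[:, perm])[0])
        np.testing.assert_allclose(stats_perm, base, rtol=1e-9)


class TestSpearmanT:
    def test_monotone_relation(self):
        x = np.arange(20.0)
        rho, p, sig = spearman_t(x, np.exp(x / 5.0))
        assert rho == pytest.approx(1.0)
        assert sig

    def test_negative_correlation_never_significant(self):
        x = np.arange(20.0)
        rho, p, sig = spearman_t(x, -x)
        assert rho == pytest.approx(-1.0)
        assert p < 1e-10 and not sig  # the positive-coefficient rule

    def test_exclusion_mask_applied(self, rng):
        x = np.arange(40.0)
        y = x.copy()
        y[:10] = -y[:10]  # corrupt an initial burn-in segment
        rho_masked, _, _ = spearman_t(x, y, exclude=np.arange(40) < 10)
        assert rho_masked == pytest.approx(1.0)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman_t(np.ones(12), np.arange(12.0))

    def test_type_one_error_calibration(self, rng):
        """At alpha = 0.05 the t-approximation rejects ~5% of null samples."""
        alpha, n_sim, n = 0.05, 2000, 20
        hits = 0
        for _ in range(n_sim):
            x, y = rng.normal(size=(2, n))
            rho, p, _ = spearman_t(x, y, alpha=alpha)
            hits += p < alpha
        assert 0.03 <= hits / n_sim <= 0.07


class TestBinomialPosthoc:
    def test_all_significant_closed_form(self):
        assert binomial_posthoc(16, 16) == pytest.approx(2.0**-16, rel=1e-12)

    def test_none_significant_is_one(self):
        assert binomial_posthoc(0, 16) == pytest.approx(1.0)

    def test_partial_matches_exact_summation(self):
        from math import comb

        expected = sum(comb(16, k) for k in range(10, 17)) / 2**16
        assert binomial_posthoc(10, 16) == pytest.approx(expected, rel=1e-12)

    def test_invalid_null_rejected(self):
        with pytest.raises(ValueError):
            binomial_posthoc(3, 10, p_null=1.5)


class TestEffectMagnitude:
    def test_clean_step(self):
        t = np.arange(0.0, 240.0, 0.5)
        v = np.where(t > 120.0, 1.0, 0.0)
        assert effect_magnitude((t, v), onset=120.0) == pytest.approx(1.0)

    def test_flat_series(self):
        t = np.arange(0.0, 240.0, 0.5)
        assert effect_magnitude((t, np.full(t.size, 2.0)), onset=120.0) == 0.0

    def test_linear_ramp_matches_direct_average(self):
        t = np.arange(0.0, 240.0, 0.25)
        m = 0.01
        v = m * (t - 120.0)
        got = effect_magnitude((t, v), onset=120.0, span=120.0)
        before = v[(t >= 0.0) & (t <= 120.0)].mean()
        after = v[(t > 120.0) & (t <= 240.0)].mean()
        assert got == pytest.approx(after - before, rel=1e-12)
        assert got == pytest.approx(m * 120.0, rel=0.01)

    def test_insufficient_coverage_rejected(self):
        t = np.arange(100.0, 140.0)
        with pytest.raises(ValueError, match="cover"):
            effect_magnitude((t, np.ones(t.size)), onset=120.0, span=120.0)


class TestRobustnessExperiment:
    def test_structure_and_determinism_of_clean_column(self):
        ibi = build_ibi(ipfm_beats(cold_pressor(seed=2)))
        curves = robustness_experiment(
            ibi, onset=120.0, methods=("exact", "robust"),
            n_range=(0, 2), reps=3, seed=0,
        )
        assert set(curves) == {"exact", "robust"}
        for curve in curves.values():
            assert curve.effects.shape == (3, 2)
            # no randomness at n = 0: the column repeats one value
            assert np.ptp(curve.effects[:, 0]) == 0.0
            assert curve.mad_per_n[0] == 0.0
            assert curve.clean_effect > 0  # sympathetic onset raises CSI
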