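"""Family algebra, fitting, goodness of fit and model selection."""

import math

import numpy as np
import pytest
from scipy import stats

from ecorisk.distributions import (
    ALL_FAMILIES,
    Family,
    FitError,
    FittedDistribution,
    GofReport,
    ad_statistic,
    ad_test,
    aic,
    fit_mle,
    ks_test,
    rank_fits,
    select_model,
)

REFERENCE_PARAMS = {
    Family.LOG_NORMAL: (0.5, 0.8),
    Family.LOG_LOGISTIC: (10.0, 4.0),
    Family.WEIBULL: (2.0, 1.5),
    Family.BURR3: (5.0, 3.0, 0.7),
}


def _dist(family, params=None):
    return FittedDistribution(family=family, params=params or REFERENCE_PARAMS[family])


class TestClosedForms:
    def test_log_logistic_median_is_scale(self):
        d = _dist(Family.LOG_LOGISTIC, (7.3, 2.2))
        assert d.cdf(7.3) == pytest.approx(0.5, abs=1e-12)

    def test_burr3_cdf_at_scale(self):
        b, c, k = 4.0, 2.0, 1.7
        assert _dist(Family.BURR3, (b, c, k)).cdf(b) == pytest.approx(2.0**-k, rel=1e-12)

    def test_burr3_with_unit_k_equals_log_logistic(self, rng):
        """Burr III reduces to the log-logistic on its k = 1 slice."""
        ll = _dist(Family.LOG_LOGISTIC, (3.0, 2.5))
        burr = _dist(Family.BURR3, (3.0, 2.5, 1.0))
        x = rng.uniform(0.05, 30.0, 20)
        assert np.max(np.abs(ll.cdf(x) - burr.cdf(x))) < 1e-10

    def test_log_logistic_hc5_closed_form(self):
        d = _dist(Family.LOG_LOGISTIC, (1.0, 1.0))
        assert d.quantile(0.05) == pytest.approx(1.0 / 19.0, rel=1e-9)

    def test_weibull_unit_median(self):
        assert _dist(Family.WEIBULL, (1.0, 1.0)).quantile(0.5) == pytest.approx(math.log(2))

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_quantile_inverts_cdf(self, family):
        d = _dist(family)
        p = np.linspace(0.001, 0.999, 41)
        x = d.quantile(p)
        assert np.allclose(d.cdf(x), p, rtol=1e-9, atol=1e-12)
        assert np.all(np.diff(x) > 0)  # cdf monotone <=> quantile increasing

    def test_domain_errors(self):
        d = _dist(Family.LOG_LOGISTIC)
        with pytest.raises(ValueError):
            d.cdf(-1.0)
        with pytest.raises(ValueError):
            d.quantile(1.0)


class TestSampling:
    def test_same_seed_same_stream(self):
        d = _dist(Family.WEIBULL)
        assert np.array_equal(d.sample(1000, seed=42), d.sample(1000, seed=42))

    def test_empirical_median(self):
        d = _dist(Family.LOG_LOGISTIC, (1.0, 4.0))
        x = d.sample(100_000, seed=5)
        assert np.median(x) == pytest.approx(1.0, rel=0.01)

    def test_empirical_cdf_converges(self):
        """Glivenko–Cantelli: the empirical cdf at the scale tends to 1/2."""
        d = _dist(Family.LOG_LOGISTIC, (2.0, 3.0))
        x = d.sample(10_000, seed=6)
        assert np.mean(x <= 2.0) == pytest.approx(0.5, abs=0.02)

    def test_rejects_empty_sample(self):
        with pytest.raises(ValueError):
            _dist(Family.WEIBULL).sample(0, seed=1)


class TestFitting:
    def test_log_logistic_parameter_recovery(self):
        true = _dist(Family.LOG_LOGISTIC, (10.0, 5.0))
        fit = fit_mle(Family.LOG_LOGISTIC, true.sample(500, seed=1))
        alpha, beta = fit.params
        assert alpha == pytest.approx(10.0, rel=0.05)
        assert beta == pytest.approx(5.0, rel=0.15)

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_recovery_all_families(self, family):
        """Median scale error < 10% and shape error < 20% over 20 seeds (n=500)."""
        true = _dist(family)
        scale_err, shape_err = [], []
        for seed in range(20):
            fit = fit_mle(family, true.sample(500, seed=seed))
            true_p, est_p = np.asarray(true.params), np.asarray(fit.params)
            if family is Family.LOG_NORMAL:
                # location μ is log-scale: compare on the concentration scale
                scale_err.append(abs(math.exp(est_p[0]) - math.exp(true_p[0])) / math.exp(true_p[0]))
                shape_err.append(abs(est_p[1] - true_p[1]) / true_p[1])
            else:
                scale_err.append(abs(est_p[0] - true_p[0]) / true_p[0])
                shape_err.append(np.max(np.abs(est_p[1:] - true_p[1:]) / true_p[1:]))
        assert np.median(scale_err) < 0.10
        assert np.median(shape_err) < 0.20

    def test_constant_data_unfittable(self):
        with pytest.raises(FitError, match="constant"):
            fit_mle(Family.LOG_NORMAL, np.full(10, 3.0))

    def test_rejects_nonpositive_and_tiny_samples(self):
        with pytest.raises(FitError):
            fit_mle(Family.WEIBULL, [1.0, -2.0, 3.0])
        with pytest.raises(FitError):
            fit_mle(Family.WEIBULL, [1.0, 2.0])

    def test_burr_on_log_logistic_data_near_nested_slice(self):
        """On log-logistic data the Burr III outer shape sits near k = 1 or is flagged."""
        true = _dist(Family.LOG_LOGISTIC, (10.0, 5.0))
        fit = fit_mle(Family.BURR3, true.sample(500, seed=3))
        assert fit.limit_flag or 0.2 < fit.params[2] < 5.0


class TestGoodnessOfFit:
    def test_ks_at_constructed_minimum(self):
        """Data placed at the (i-1/2)/n quantiles attain D = 1/(2n)."""
        d = _dist(Family.LOG_LOGISTIC, (5.0, 3.0))
        n = 20
        x = d.quantile((np.arange(1, n + 1) - 0.5) / n)
        D, p = ks_test(d, x)
        assert D == pytest.approx(0.5 / n, abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_ks_discriminates_misspecification(self):
        """KS D under the wrong family stochastically dominates D under the truth."""
        true = _dist(Family.LOG_LOGISTIC, (10.0, 1.2))
        d_true, d_wrong = [], []
        for seed in range(40):
            x = true.sample(100, seed=seed)
            d_true.append(ks_test(fit_mle(Family.LOG_LOGISTIC, x), x)[0])
            d_wrong.append(ks_test(fit_mle(Family.WEIBULL, x), x)[0])
        assert np.mean(d_wrong) > np.mean(d_true)
        assert np.mean(np.asarray(d_wrong) > np.asarray(d_true)) > 0.6

    def test_ad_statistic_matches_bruteforce_sum(self, rng):
        d = _dist(Family.WEIBULL, (2.0, 1.5))
        x = d.sample(15, seed=9)
        u = np.sort(d.cdf(np.sort(x)))
        n = len(u)
        brute = -n - sum(
            (2 * (i + 1) - 1) / n * (math.log(u[i]) + math.log(1 - u[n - 1 - i]))
            for i in range(n)
        )
        assert ad_statistic(d, x) == pytest.approx(brute, rel=1e-12)

    def test_ad_constructed_quantiles_attain_minimum(self):
        """The mid-quantile configuration minimizes A² over random datasets."""
        d = _dist(Family.LOG_LOGISTIC, (5.0, 3.0))
        n = 12
        a2_min = ad_statistic(d, d.quantile((np.arange(1, n + 1) - 0.5) / n))
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert ad_statistic(d, d.sample(n, rng)) >= a2_min - 1e-12

    def test_ad_larger_under_misspecification(self):
        true = _dist(Family.LOG_LOGISTIC, (10.0, 1.2))
        a_true, a_wrong = [], []
        for seed in range(30):
            x = true.sample(100, seed=seed)
            a_true.append(ad_statistic(fit_mle(Family.LOG_LOGISTIC, x), x))
            a_wrong.append(ad_statistic(fit_mle(Family.WEIBULL, x), x))
        assert np.mean(a_wrong) > np.mean(a_true)

    def test_ad_bootstrap_p_deterministic(self):
        d = _dist(Family.LOG_LOGISTIC, (5.0, 3.0))
        x = d.sample(25, seed=4)
        fit = fit_mle(Family.LOG_LOGISTIC, x)
        assert ad_test(fit, x, n_boot=49, seed=8) == ad_test(fit, x, n_boot=49, seed=8)
        p = ad_test(fit, x, n_boot=49, seed=8)[1]
        assert 0.0 < p <= 1.0


class TestSelection:
    def test_aic_formula(self):
        d = FittedDistribution(Family.LOG_LOGISTIC, (1.0, 1.0), log_likelihood=-100.0, n=10)
        assert aic(d) == pytest.approx(204.0)
        b = FittedDistribution(Family.BURR3, (1.0, 1.0, 1.0), log_likelihood=-100.0, n=10)
        assert aic(b) == aic(d) + 2.0  # extra parameter costs 2 at equal likelihood

    def test_aic_permutation_invariant(self, rng):
        x = _dist(Family.WEIBULL).sample(80, seed=2)
        a1 = aic(fit_mle(Family.WEIBULL, x))
        rng.shuffle(x)
        assert aic(fit_mle(Family.WEIBULL, x)) == pytest.approx(a1, rel=1e-9)

    def test_single_family_returned(self):
        x = _dist(Family.LOG_NORMAL).sample(50, seed=1)
        best, ranking = select_model(x, families=[Family.LOG_NORMAL])
        assert best.family is Family.LOG_NORMAL
        assert len(ranking) == 1

    def test_true_family_selected_majority(self):
        """KS selection finds the generating family in most replicates."""
        true = _dist(Family.LOG_LOGISTIC, (10.0, 1.2))
        hits = 0
        for seed in range(20):
            best, _ = select_model(
                true.sample(200, seed=seed),
                families=[Family.LOG_LOGISTIC, Family.WEIBULL],
                criterion="ks_p",
            )
            hits += best.family is Family.LOG_LOGISTIC
        assert hits >= 14

    def test_limit_flagged_fit_excluded_from_ranking(self):
        x = _dist(Family.LOG_LOGISTIC, (10.0, 4.0)).sample(60, seed=5)
        good = fit_mle(Family.LOG_LOGISTIC, x)
        import dataclasses

        bad = dataclasses.replace(fit_mle(Family.BURR3, x), limit_flag=True)
        best, ranking = rank_fits([good, bad], x, criterion="ks_p")
        assert best.family is Family.LOG_LOGISTIC
        assert [r.family for r in ranking] == [Family.LOG_LOGISTIC]

    def test_all_failures_reported(self):
        with pytest.raises(FitError, match="constant"):
            select_model(np.full(10, 2.0), families=[Family.WEIBULL, Family.LOG_NORMAL])
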