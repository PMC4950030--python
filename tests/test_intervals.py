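import warnings

import numpy as np
import pytest
from scipy import stats

from hetvar.data_model import (
    ESTIMATOR_TAGS,
    INTERVAL_TAGS,
    EstimatorOptions,
    Tau2Interval,
)
from hetvar.intervals import (
    IntervalPointMismatchWarning,
    _check_point,
    ci_bj,
    ci_bootstrap,
    ci_bt,
    ci_jackson,
    ci_pl,
    ci_qp,
    ci_sj,
    ci_wald,
    compatibility,
    compatibility_matrix,
)
from hetvar.likelihood_estimators import profile_log_likelihood
from hetvar.moment_estimators import estimate_pm
from hetvar.pooling import WeightingScheme, cochran_q, generalized_q, q_gen
from hetvar.qdist import gamma_moments, mixture_cdf, mixture_coefficients

from conftest import random_dataset


class TestQProfile:
    def test_f1_bounds(self, f1):
        iv = ci_qp(f1)
        assert iv.lower == 0.0
        # independent oracle: solve 0.5/(0.1+t) = chi2_{2,0.025} directly
        upper_oracle = 0.5 / stats.chi2.ppf(0.025, 2) - 0.1
        assert iv.upper == pytest.approx(upper_oracle, abs=1e-6)

    def test_homogeneous_null_set(self, f0):
        iv = ci_qp(f0)
        assert iv.degenerate and iv.lower == iv.upper == 0.0

    def test_endpoint_identities(self, f2):
        iv = ci_qp(f2)
        assert q_gen(f2, iv.upper) == pytest.approx(
            stats.chi2.ppf(0.025, 2), abs=1e-6)

    def test_contains_pm_estimate(self, f1, f2):
        for d in (f1, f2):
            iv = ci_qp(d)
            assert iv.contains(estimate_pm(d).tau2)

    def test_contains_pm_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = random_dataset(rng, k=int(rng.integers(3, 9)))
            iv = ci_qp(d)
            if not iv.degenerate:
                assert iv.contains(estimate_pm(d).tau2)

    def test_nesting_across_levels(self, f1):
        iv95 = ci_qp(f1, level=0.95)
        iv99 = ci_qp(f1, level=0.99)
        assert iv99.lower <= iv95.lower and iv95.upper <= iv99.upper


class TestProfileLikelihood:
    def test_boundary_lower_at_zero_mle(self, f0):
        iv = ci_pl(f0)
        assert iv.lower == 0.0

    def test_bounds_satisfy_drop_equation(self, f1):
        iv = ci_pl(f1)
        from hetvar.likelihood_estimators import estimate_ml

        cutoff = (profile_log_likelihood(f1, estimate_ml(f1).tau2)
                  - 0.5 * stats.chi2.ppf(0.95, 1))
        assert profile_log_likelihood(f1, iv.upper) == pytest.approx(
            cutoff, abs=1e-6)

    def test_nesting(self, f1):
        iv95, iv99 = ci_pl(f1, 0.95), ci_pl(f1, 0.99)
        assert iv99.upper >= iv95.upper and iv99.lower <= iv95.lower


class TestWald:
    def test_ml_f1_frozen(self, f1):
        # 1/15 +/- 1.96 sqrt(2/108), truncated at zero
        iv = ci_wald(f1, kind="ML")
        half = stats.norm.ppf(0.975) * np.sqrt(2 / 108)
        assert iv.lower == 0.0
        assert iv.upper == pytest.approx(1 / 15 + half, rel=1e-6)

    def test_width_scales_with_z(self, f2):
        iv90 = ci_wald(f2, level=0.90, kind="REML")
        iv99 = ci_wald(f2, level=0.99, kind="REML")
        ratio = stats.norm.ppf(0.995) / stats.norm.ppf(0.95)
        # upper bounds are est + z*sd, so differences scale exactly with z
        est = iv90.point_estimate
        assert (iv99.upper - est) / (iv90.upper - est) == pytest.approx(ratio)

    def test_reml_uses_reml_variance(self, f2):
        from hetvar.likelihood_estimators import asymptotic_variance, estimate_reml

        est = estimate_reml(f2)
        half = stats.norm.ppf(0.975) * np.sqrt(
            asymptotic_variance(f2, est.tau2, "REML").var_tau2)
        iv = ci_wald(f2, kind="REML")
        assert iv.upper == pytest.approx(est.tau2 + half, rel=1e-9)


class TestBiggerstaffTweedie:
    def test_tail_residuals(self, f2):
        iv = ci_bt(f2)
        q = cochran_q(f2)
        g_up = gamma_moments(f2, iv.upper)
        assert stats.gamma.cdf(q / g_up.lam, a=g_up.r) == pytest.approx(
            0.025, abs=1e-6)
        if iv.lower > 0:
            g_lo = gamma_moments(f2, iv.lower)
            assert stats.gamma.sf(q / g_lo.lam, a=g_lo.r) == pytest.approx(
                0.025, abs=1e-6)

    def test_homogeneous_null_set(self, f0):
        iv = ci_bt(f0)
        assert iv.degenerate


class TestMixtureIntervals:
    def test_bj_dl_residuals(self, f2):
        iv = ci_bj(f2, statistic="DL")
        q = cochran_q(f2)
        scheme = WeightingScheme.fixed_effect()
        up = mixture_cdf(mixture_coefficients(f2, iv.upper, scheme), q)
        assert up == pytest.approx(0.025, abs=1e-6)
        assert iv.lower == 0.0   # F2 is mildly heterogeneous

    def test_bj_zero_truncation_branch(self, f1):
        iv = ci_bj(f1)
        assert iv.lower == 0.0

    def test_bj_hm_equivalent_to_q_inversion(self, f2):
        # the HM functional is monotone in Q, so inverting its distribution
        # reproduces the Q-based bounds exactly
        assert ci_bj(f2, statistic="HM").upper == pytest.approx(
            ci_bj(f2, statistic="DL").upper, rel=1e-6)

    def test_jackson_residuals(self, f2):
        iv = ci_jackson(f2)
        scheme = WeightingScheme.reciprocal_se()
        qa = generalized_q(f2, scheme)
        up = mixture_cdf(mixture_coefficients(f2, iv.upper, scheme), qa)
        assert up == pytest.approx(0.025, abs=1e-6)

    def test_jackson_with_fe_weights_is_bj(self, f2):
        iv = ci_jackson(f2, scheme=WeightingScheme.fixed_effect())
        bj = ci_bj(f2, statistic="DL")
        assert iv.upper == pytest.approx(bj.upper, rel=1e-8)
        assert iv.lower == pytest.approx(bj.lower, abs=1e-10)

    def test_homogeneous_branches(self, f0):
        for iv in (ci_bj(f0), ci_jackson(f0)):
            assert iv.degenerate or iv.lower == 0.0


class TestSidikJonkmanInterval:
    def test_frozen_values(self, f1):
        iv = ci_sj(f1)
        assert iv.lower == pytest.approx(2 * 0.15625 / stats.chi2.ppf(0.975, 2))
        assert iv.upper == pytest.approx(2 * 0.15625 / stats.chi2.ppf(0.025, 2))

    def test_never_covers_zero(self):
        rng = np.random.default_rng(8)
        for _ in range(15):
            d = random_dataset(rng, k=int(rng.integers(3, 8)), tau2=0.0)
            iv = ci_sj(d)
            assert iv.lower > 0.0

    def test_scales_linearly_in_estimate(self, f1, f2):
        from hetvar.auxiliary_estimators import estimate_sj

        for d in (f1, f2):
            iv = ci_sj(d)
            est = estimate_sj(d).tau2
            assert iv.upper / iv.lower == pytest.approx(
                stats.chi2.ppf(0.975, d.k - 1) / stats.chi2.ppf(0.025, d.k - 1))
            assert iv.lower == pytest.approx(
                (d.k - 1) * est / stats.chi2.ppf(0.975, d.k - 1))


class TestBootstrap:
    def test_homogeneous_nonparametric_collapses(self, f0):
        iv = ci_bootstrap(f0, opts=EstimatorOptions(B=100, seed=2))
        assert iv.lower == iv.upper == 0.0

    def test_seed_determinism(self, f2):
        opts = EstimatorOptions(B=200, seed=77)
        a = ci_bootstrap(f2, mode="parametric", opts=opts)
        b = ci_bootstrap(f2, mode="parametric", opts=opts)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_parametric_approaches_sampling_quantiles(self, f1):
        """Percentile bounds track the base estimator's sampling quantiles."""
        from hetvar.moment_estimators import estimate_dl
        from hetvar.data_model import MetaDataset
        from hetvar.pooling import pooled_effect

        point = estimate_dl(f1).tau2
        mu = pooled_effect(f1, point).mu
        rng = np.random.default_rng(123)
        draws = []
        for _ in range(4000):
            y = rng.normal(mu, np.sqrt(point + f1.v))
            draws.append(estimate_dl(MetaDataset.from_arrays(y, f1.v)).tau2)
        lo_mc, hi_mc = np.percentile(draws, [2.5, 97.5])
        iv = ci_bootstrap(f1, mode="parametric",
                          opts=EstimatorOptions(B=4000, seed=5))
        assert iv.lower == pytest.approx(lo_mc, abs=0.02)
        assert iv.upper == pytest.approx(hi_mc, rel=0.15)


class TestCompatibility:
    def test_reference_cells(self):
        assert compatibility("PM", "QP") == "natural"
        assert compatibility("FB", "Wt_ML") == "incompatible"
        assert compatibility("ML", "PL") == "natural"
        assert compatibility("SJ", "SJ") == "natural"
        assert compatibility("RB0", "Credible") == "natural"
        assert compatibility("DL", "QP") == "in_principle"
        assert compatibility("DL", "PL") == "incompatible"

    def test_fb_pairs_only_with_credible(self):
        for iv in INTERVAL_TAGS:
            klass = compatibility("FB", iv)
            assert (klass == "natural") == (iv == "Credible")
            if iv != "Credible":
                assert klass == "incompatible"

    def test_matrix_complete(self):
        m = compatibility_matrix()
        assert set(m) == {(e, i) for e in ESTIMATOR_TAGS for i in INTERVAL_TAGS}
        assert set(m.values()) <= {"natural", "in_principle", "incompatible"}

    def test_unknown_tags(self):
        with pytest.raises(KeyError):
            compatibility("XX", "QP")
        with pytest.raises(KeyError):
            compatibility("DL", "XX")


def test_warning_when_interval_excludes_point():
    iv = Tau2Interval(method="BJ_DL", level=0.95, lower=0.2, upper=0.4,
                      point_method="DL", point_estimate=0.05)
    with pytest.warns(IntervalPointMismatchWarning):
        _check_point(iv)
    contained = Tau2Interval(method="BJ_DL", level=0.95, lower=0.0, upper=0.4,
                             point_method="DL", point_estimate=0.05)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        _check_point(contained)
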