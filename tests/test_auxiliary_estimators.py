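import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hetvar.auxiliary_estimators import (
    bm_closed_form,
    estimate_bm,
    estimate_dlb,
    estimate_rb,
    estimate_rbp,
    estimate_sj,
    iterated_sj,
    rbp_prior_mean,
    sj_weights,
)
from hetvar.data_model import (
    EstimatorOptions,
    MetaDataset,
    MissingSampleSizesError,
    ValidationError,
)
from hetvar.likelihood_estimators import estimate_ml
from hetvar.moment_estimators import estimate_dl, estimate_pm

from conftest import random_dataset
from test_likelihood_estimators import grid_maximize


@st.composite
def datasets(draw, **kw):
    seed = draw(st.integers(0, 2**31 - 1))
    k = draw(st.integers(3, 8))
    return random_dataset(np.random.default_rng(seed), k=k, **kw)


class TestSidikJonkman:
    def test_original_variant_value(self, f1):
        # tau0^2 = 0.5/3, q_i = 1.6, estimate = (1/2)(0.5/1.6)
        w = sj_weights(f1, "original")
        assert w.tau0_sq == pytest.approx(1 / 6)
        np.testing.assert_allclose(w.q, 1.6)
        assert estimate_sj(f1).tau2 == pytest.approx(0.15625)

    def test_original_variant_rejects_identical_effects(self, f0):
        with pytest.raises(ValidationError, match="improved"):
            estimate_sj(f0, EstimatorOptions(sj_variant="original"))

    def test_improved_variant_substitution(self, f0):
        # identical effects make the weighted sum of squares exactly zero,
        # so the improved variant runs (no degenerate-tau0 error) but its
        # positivity guarantee only applies to non-degenerate inputs
        est = estimate_sj(f0, EstimatorOptions(sj_variant="improved"))
        assert est.tau2 == 0.0

    def test_improved_variant_positive_when_ho_truncates(self):
        # nearly identical effects: HO truncates to zero, the 0.01
        # substitution still yields a strictly positive SJ estimate
        d = MetaDataset.from_arrays([0.49, 0.5, 0.51], [0.1, 0.1, 0.1])
        from hetvar.moment_estimators import estimate_ho

        assert estimate_ho(d).tau2 == 0.0
        est = estimate_sj(d, EstimatorOptions(sj_variant="improved"))
        assert est.tau2 > 0

    @given(datasets())
    def test_always_positive(self, data):
        assert estimate_sj(data).tau2 > 0

    @given(datasets())
    def test_iterated_sj_is_pm(self, data):
        it = iterated_sj(data)
        pm = estimate_pm(data)
        assert it.tau2 == pytest.approx(pm.tau2, abs=1e-7)

    def test_iterated_sj_equals_pm_on_f2(self, f2):
        assert iterated_sj(f2).tau2 == pytest.approx(
            estimate_pm(f2).tau2, abs=1e-8)


class TestRukhinBayes:
    @staticmethod
    def _oracle(data, prior):
        """Inline evaluation of the adopted Bayes-estimator grouping."""
        k, n_tot = data.k, data.n.sum()
        syy = ((data.y - data.y.mean()) ** 2).sum()
        term = (2 * k * (n_tot - k) * prior - (k - 1) * data.v.sum()) / (
            (n_tot + k) * (k + 1))
        return syy / (k + 1) + term

    def test_missing_n_raises(self, f1):
        with pytest.raises(MissingSampleSizesError, match="sample sizes"):
            estimate_rb(f1, 0.0)

    def test_zero_prior_drops_prior_term(self, f2):
        # with prior mean 0 the estimate must not depend on the prior scale
        est0 = estimate_rb(f2, 0.0)
        assert est0.tau2_untruncated == pytest.approx(self._oracle(f2, 0.0))

    def test_homogeneous_truncates_to_zero(self):
        d = MetaDataset.from_arrays([0.5, 0.5, 0.5], [0.1, 0.1, 0.1],
                                    n=[10, 10, 10])
        est = estimate_rb(d, 0.0)
        assert est.tau2 == 0.0 and est.truncated

    def test_f2_matches_oracle(self, f2):
        assert estimate_rb(f2, 0.0).tau2 == pytest.approx(
            max(0.0, self._oracle(f2, 0.0)), rel=1e-12)
        assert estimate_rbp(f2).tau2 == pytest.approx(
            self._oracle(f2, rbp_prior_mean(f2)), rel=1e-12)

    @given(datasets(with_n=True))
    def test_rbp_positive_and_dominates_rb0(self, data):
        rbp = estimate_rbp(data)
        rb0 = estimate_rb(data, 0.0)
        assert rbp.tau2 > 0
        assert rbp.tau2 >= rb0.tau2

    def test_rbp_positive_on_homogeneous_data(self):
        d = MetaDataset.from_arrays([0.5, 0.5, 0.5], [0.1, 0.1, 0.1],
                                    n=[10, 10, 10])
        assert estimate_rbp(d).tau2 > 0


class TestBayesModal:
    def test_positive_on_homogeneous_data(self, f0):
        assert estimate_bm(f0).tau2 > 0

    def test_dominates_ml(self, f1):
        assert estimate_bm(f1).tau2 >= 1 / 15

    @given(datasets())
    def test_dominates_ml_everywhere(self, data):
        assert estimate_bm(data).tau2 >= estimate_ml(data).tau2 - 1e-10

    @given(datasets())
    def test_matches_grid_maximiser_of_penalised_likelihood(self, data):
        from hetvar.auxiliary_estimators import _penalised_profile

        est = estimate_bm(data)
        hi = max(1.0, 4 * np.sqrt(data.v.max()))
        oracle_tau = grid_maximize(lambda t: _penalised_profile(data, t),
                                   1e-9, hi)
        assert est.tau2 == pytest.approx(oracle_tau**2, abs=1e-6)

    def test_closed_form_cross_check(self, f1):
        # Taylor approximation: same order of magnitude, loose agreement
        assert bm_closed_form(f1) == pytest.approx(estimate_bm(f1).tau2,
                                                   rel=0.5)


class TestBootstrapDL:
    def test_homogeneous_always_zero(self, f0):
        est = estimate_dlb(f0, EstimatorOptions(B=50, seed=4))
        assert est.tau2 == 0.0

    def test_identity_resample_reproduces_dl(self, f1):
        # find a seed whose single resample is the identity permutation
        for seed in range(500):
            rng = np.random.default_rng(seed)
            if list(rng.integers(0, 3, size=(1, 3))[0]) == [0, 1, 2]:
                est = estimate_dlb(f1, EstimatorOptions(B=1, seed=seed))
                assert est.tau2 == pytest.approx(estimate_dl(f1).tau2)
                return
        pytest.fail("no identity-permutation seed found in 500 tries")

    def test_seed_reproducibility(self, f2):
        opts = EstimatorOptions(B=300, seed=123)
        a = estimate_dlb(f2, opts).tau2
        b = estimate_dlb(f2, opts).tau2
        assert a == b

    def test_large_b_approaches_resampling_mean(self, f2):
        """DLb converges to the mean of DL over the resampling distribution."""
        # oracle: enumerate all 3^3 equally likely resamples of k=3 studies
        import itertools

        vals = []
        for idx in itertools.product(range(3), repeat=3):
            try:
                vals.append(estimate_dl(f2.resample(idx)).tau2)
            except Exception:
                pass
        exact = np.mean(vals)
        est = estimate_dlb(f2, EstimatorOptions(B=4000, seed=9)).tau2
        se = np.std(vals) / np.sqrt(4000)
        assert est == pytest.approx(exact, abs=4 * se)

    def test_generalises_to_other_bases(self, f2):
        est = estimate_dlb(f2, EstimatorOptions(B=20, seed=5), base="HO")
        assert est.tau2 >= 0
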