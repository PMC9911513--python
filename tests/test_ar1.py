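"""AR(1) oracle tests: simulator moments, summaries, closed forms, bounds."""

import numpy as np
import pytest
from scipy import stats

from predabc import (
    DiscrepancySpec,
    GaussianProposal,
    KernelSpec,
    SingleKernelRule,
    UniformBoxPrior,
    abc_f_predict,
    abc_importance,
)
from predabc.ar1 import (
    AR1Model,
    ar1_abc_posterior_c,
    ar1_acceptance_bound,
    ar1_covariance,
    ar1_mean_vector,
    ar1_predictive_oracle,
    ar1_summaries,
    ar1_summary_spec,
)


@pytest.fixture(scope="module")
def observed():
    model = AR1Model(phi=0.5, sigma2=1.0, n=100, n_future=1)
    rng = np.random.default_rng(123)
    return model.simulate_obs(np.array([1.0]), rng).y


class TestSimulator:
    def test_iid_case_mean(self):
        # phi = 0 makes the data i.i.d. N(c, sigma^2)
        model = AR1Model(phi=0.0, sigma2=1.0, n=2, n_future=0)
        rng = np.random.default_rng(0)
        draws = np.array([model.simulate_obs(np.array([1.0]), rng).y
                          for _ in range(20_000)])
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 1.0) < 3 * se

    def test_unrolled_mean_recursion(self):
        # E[y_n] = c (1 - phi^n) / (1 - phi) from y_0 = 0
        model = AR1Model(phi=0.5, sigma2=1.0, n=5, n_future=0)
        rng = np.random.default_rng(1)
        yn = np.array([model.simulate_obs(np.array([1.0]), rng).y[-1]
                       for _ in range(50_000)])
        se = yn.std() / np.sqrt(yn.size)
        assert abs(yn.mean() - 1.9375) < 3 * se

    def test_mean_and_covariance_formulas(self):
        # the closed-form moment helpers match large-sample simulation
        model = AR1Model(phi=0.5, sigma2=1.0, n=4, n_future=0)
        rng = np.random.default_rng(2)
        sims = np.array([model.simulate_obs(np.array([0.7]), rng).y
                         for _ in range(60_000)])
        assert np.allclose(sims.mean(axis=0), 0.7 * ar1_mean_vector(4, 0.5),
                           atol=0.03)
        assert np.allclose(np.cov(sims, rowvar=False),
                           ar1_covariance(4, 0.5, 1.0), atol=0.05)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            AR1Model(phi=0.5, sigma2=0.0, n=100)
        with pytest.raises(ValueError):
            AR1Model(phi=0.5, sigma2=1.0, n=1)


class TestSummaries:
    def test_phi_zero_is_sample_mean(self):
        y = np.array([1.0, 4.0, -2.0])
        assert ar1_summaries(y, 0.0, "s1")[0] == pytest.approx(y.mean())

    def test_hand_arithmetic(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ar1_summaries(y, 0.5, "s1")[0] == pytest.approx(1.5)
        assert ar1_summaries(y, 0.5, "s3")[0] == pytest.approx(3.0)
        assert np.allclose(ar1_summaries(y, 0.5, "s2"), [1.5, 3.0])

    def test_shapes(self, observed):
        assert ar1_summaries(observed, 0.5, "s1").shape == (1,)
        assert ar1_summaries(observed, 0.5, "s2").shape == (2,)
        assert ar1_summaries(observed, 0.5, "s3").shape == (1,)

    def test_too_short(self):
        with pytest.raises(ValueError):
            ar1_summaries(np.array([1.0]), 0.5, "s1")


class TestPosteriorOracle:
    def test_exact_posterior_variance(self):
        d = ar1_abc_posterior_c(1.5, 1.0, 100, 0.0)
        assert d.mean == 1.5 and d.variance == pytest.approx(0.01)

    def test_kernel_inflation(self):
        d = ar1_abc_posterior_c(1.5, 1.0, 100, 0.1)
        assert d.variance == pytest.approx(0.02)

    def test_negative_bandwidth(self):
        with pytest.raises(ValueError):
            ar1_abc_posterior_c(0.0, 1.0, 10, -0.1)

    def test_conditioning_routine_reproduces_closed_form(self, observed):
        # the generic flat-prior Gaussian conditioning applied to the s1
        # summary row must reproduce the printed posterior for any h
        from predabc.gaussian import FlatLocationGaussian

        n = observed.size
        joint = FlatLocationGaussian(ar1_mean_vector(n, 0.5),
                                     ar1_covariance(n, 0.5, 1.0))
        a = np.full(n, 0.5 / n)
        a[-1] = 1.0 / n
        for h in (0.0, 0.1, 0.5):
            got = joint.condition_scalar(a[None, :], a @ observed, h=h, a_c=1.0)
            ref = ar1_abc_posterior_c(float(a @ observed), 1.0, n, h)
            assert got.mean == pytest.approx(ref.mean, abs=1e-10)
            assert got.variance == pytest.approx(ref.variance, abs=1e-10)


class TestPredictiveOracle:
    def test_abc_f_closed_form(self, observed):
        yring = float(ar1_summaries(observed, 0.5, "s3")[0])
        d0 = ar1_predictive_oracle(observed, 0.5, 1.0, 0.0, "abc_f")
        assert d0.mean == pytest.approx(yring)
        assert d0.variance == pytest.approx(1.01)
        dh = ar1_predictive_oracle(observed, 0.5, 1.0, 0.3, "abc_f")
        assert dh.variance == pytest.approx(1.01 + 0.09)

    def test_s3_and_s2_exact_at_zero_bandwidth(self, observed):
        exact = ar1_predictive_oracle(observed, 0.5, 1.0, 0.0, "exact")
        for variant in ("s3", "s2"):
            d = ar1_predictive_oracle(observed, 0.5, 1.0, 0.0, variant)
            assert d.mean == pytest.approx(exact.mean, abs=1e-8)
            assert d.variance == pytest.approx(exact.variance, abs=1e-8)

    def test_s1_only_variance_dominates(self, observed):
        exact = ar1_predictive_oracle(observed, 0.5, 1.0, 0.0, "exact")
        d = ar1_predictive_oracle(observed, 0.5, 1.0, 0.0, "s1_only")
        assert d.variance > exact.variance

    def test_s1_only_equals_exact_when_iid(self):
        # phi = 0: the data are i.i.d., parameter sufficiency implies
        # predictive sufficiency and the inflation disappears
        rng = np.random.default_rng(3)
        y = rng.normal(1.0, 1.0, size=50)
        exact = ar1_predictive_oracle(y, 0.0, 1.0, 0.0, "exact")
        d = ar1_predictive_oracle(y, 0.0, 1.0, 0.0, "s1_only")
        assert d.mean == pytest.approx(exact.mean, abs=1e-8)
        assert d.variance == pytest.approx(exact.variance, abs=1e-8)

    def test_frozen_regression_values(self):
        # frozen outputs of the conditioning reconstruction on a fixed dataset;
        # the s3 values independently equal the printed two-stage form
        # N(yring, sigma^2 (1 + 1/n) + h^2) = N(2.23, 1.24)
        y = np.array([0.5, 1.2, 2.0, 1.1, 2.5])
        d1 = ar1_predictive_oracle(y, 0.5, 1.0, 0.2, "s1_only")
        d3 = ar1_predictive_oracle(y, 0.5, 1.0, 0.2, "s3")
        assert (d1.mean, d1.variance) == pytest.approx(
            (1.9293750000000003, 1.5003515625000001), abs=1e-9)
        assert (d3.mean, d3.variance) == pytest.approx((2.23, 1.24), abs=1e-9)


class TestAcceptanceBound:
    def test_root_n_scaling_at_unit_phi(self):
        b1, d1 = ar1_acceptance_bound(1.0, 1.0, 25, 0.1)
        b2, d2 = ar1_acceptance_bound(1.0, 1.0, 100, 0.1)
        assert d1 == d2 == "upper"
        assert b2 == pytest.approx(b1 / 2.0)

    def test_stationary_branch_arithmetic(self):
        b, direction = ar1_acceptance_bound(0.0, 1.0, 10, 0.1)
        assert direction == "lower"
        expected = np.sqrt(2) * 0.1 / np.sqrt(np.pi) * np.exp(-0.005)
        assert b == pytest.approx(expected)
        assert b == pytest.approx(0.0793905, abs=1e-6)

    def test_invalid_h(self):
        with pytest.raises(ValueError):
            ar1_acceptance_bound(0.5, 1.0, 10, 0.0)

    @pytest.mark.parametrize("phi,n", [(1.2, 10), (1.0, 16), (0.5, 20)])
    def test_monte_carlo_respects_bound(self, phi, n):
        # brute-force maximization of P(|z_n - y_n| <= h) over a c-grid
        sigma2, h = 1.0, 0.1
        bound, direction = ar1_acceptance_bound(phi, sigma2, n, h)
        mu_n = float(ar1_mean_vector(n, phi)[-1])
        var_n = float(ar1_covariance(n, phi, sigma2)[-1, -1])
        y_n = 1.0
        rng = np.random.default_rng(10)
        best = 0.0
        for c in y_n / mu_n + np.linspace(-0.5, 0.5, 11) * np.sqrt(var_n) / abs(mu_n):
            z_n = c * mu_n + rng.standard_normal(100_000) * np.sqrt(var_n)
            best = max(best, float(np.mean(np.abs(z_n - y_n) <= h)))
        se = 3.0 * np.sqrt(0.25 / 100_000)
        if direction == "upper":
            assert best <= bound + se
        else:
            assert best >= bound - se


class TestSamplerVsFormula:
    def test_importance_sampling_matches_posterior_moments(self, observed):
        # Gaussian kernel on s1; weighted moments vs the closed form
        model = AR1Model(phi=0.5, sigma2=1.0, n=100, n_future=1)
        prior = UniformBoxPrior([-50.0], [50.0])
        spec = ar1_summary_spec(0.5, "s1")
        h = 0.1
        rule = SingleKernelRule(DiscrepancySpec.linf(), KernelSpec("gaussian", h))
        ybar = float(ar1_summaries(observed, 0.5, "s1")[0])
        proposal = GaussianProposal([ybar], [0.5])
        run = abc_importance(model, prior, proposal, spec, rule, observed,
                             m=40_000, seed=11)
        c, w = run.thetas[:, 0], run.weights
        target = ar1_abc_posterior_c(ybar, 1.0, 100, h)
        mean = float(np.sum(w * c))
        var = float(np.sum(w * (c - mean) ** 2))
        se_mean = np.sqrt(np.sum(w**2 * (c - mean) ** 2))
        assert abs(mean - target.mean) < 3 * se_mean
        assert var == pytest.approx(target.variance, rel=0.1)

        # ABC-F on the same parameter draws matches the predictive closed form
        pred = abc_f_predict(run, model, observed, seed=12)
        yp = pred.ytilde[:, 0]
        ptarget = ar1_predictive_oracle(observed, 0.5, 1.0, h, "abc_f")
        pmean = float(np.sum(w * yp))
        pvar = float(np.sum(w * (yp - pmean) ** 2))
        se_pmean = np.sqrt(np.sum(w**2 * (yp - pmean) ** 2))
        assert abs(pmean - ptarget.mean) < 3 * se_pmean
        assert pvar == pytest.approx(ptarget.variance, rel=0.1)

    def test_single_theta_draw_predictive_law(self):
        # with one parameter draw, ABC-F output is exactly pi(ytilde | theta, y)
        model = AR1Model(phi=0.5, sigma2=1.0, n=10, n_future=1)
        rng = np.random.default_rng(13)
        y = model.simulate_obs(np.array([1.0]), rng).y
        from predabc import WeightedSampleSet

        base = WeightedSampleSet(thetas=np.array([[1.0]]), weights=np.array([1.0]),
                                 discrepancies=np.array([0.0]))
        draws = np.array([abc_f_predict(base, model, y, seed=s).ytilde[0, 0]
                          for s in range(4000)])
        target_mean = 1.0 + 0.5 * y[-1]
        p = stats.kstest(draws, lambda x: stats.norm.cdf(x, target_mean, 1.0)).pvalue
        assert p > 0.01
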