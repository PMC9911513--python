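"""Sampler tests against the enumeration oracle and structural invariants."""

import numpy as np
import pytest
from scipy import stats

from predabc import (
    DiscrepancySpec,
    KernelSpec,
    MCMCConfig,
    SingleKernelRule,
    UniformBoxPrior,
    ZeroAcceptanceError,
    abc_f_predict,
    abc_importance,
    abc_mcmc,
    abc_rejection,
    deferred_prediction,
)
from predabc.ar1 import AR1Model, ar1_summary_spec
from predabc.mg1 import MG1Model, MG1Prior
from predabc.mg1 import mg1_summary_spec
from predabc.toy import (
    BiasedToyProposal,
    ToyModel,
    ToyPrior,
    enumerate_abc_p_joint,
    toy_summary_spec,
)

TOY = dict(model=ToyModel(), prior=ToyPrior(), spec=toy_summary_spec(),
           rule=SingleKernelRule(DiscrepancySpec.linf(), KernelSpec("uniform", 0.0)),
           y_obs=np.array([1.0]))


def _joint_freq(thetas, preds, weights=None):
    out = {}
    for k in ((0, 0), (0, 1), (1, 0), (1, 1)):
        mask = (thetas[:, 0] == k[0]) & (np.nan_to_num(preds[:, 0], nan=-1) == k[1])
        out[k] = float(np.mean(mask) if weights is None else np.sum(weights[mask]))
    return out


def _assert_matches_enumeration(freqs, m_eff):
    exact = enumerate_abc_p_joint(1.0, 0.0)
    for k, p in exact.items():
        se = np.sqrt(p * (1 - p) / m_eff)
        assert abs(freqs[k] - p) < 3 * se + 1e-3, (k, freqs[k], p)


class TestToyEnumeration:
    def test_rejection_matches(self):
        run = abc_rejection(TOY["model"], TOY["prior"], TOY["spec"], TOY["rule"],
                            TOY["y_obs"], m=30_000, seed=1, mode="P")
        _assert_matches_enumeration(_joint_freq(run.thetas, run.ytilde), len(run))

    def test_importance_with_biased_proposal_matches(self):
        run = abc_importance(TOY["model"], TOY["prior"], BiasedToyProposal(0.8),
                             TOY["spec"], TOY["rule"], TOY["y_obs"],
                             m=30_000, seed=2, mode="P")
        freqs = _joint_freq(run.thetas, run.ytilde, run.weights)
        _assert_matches_enumeration(freqs, run.ess)

    def test_mcmc_matches(self):
        cfg = MCMCConfig(iterations=50_000, burn_in=2000,
                         propose=lambda th, rng: np.array([float(rng.integers(0, 2))]))
        run = abc_mcmc(TOY["model"], TOY["prior"], TOY["spec"], TOY["rule"],
                       TOY["y_obs"], cfg, seed=3, mode="P")
        # correlated draws: use a conservative effective size
        _assert_matches_enumeration(_joint_freq(run.thetas, run.ytilde),
                                    len(run) / 4)

    def test_importance_weight_formula(self):
        # the weight is K_h(Delta) * prior / proposal -- nothing else: check
        # every record against the recomputed formula
        prior, q = ToyPrior(), BiasedToyProposal(0.7)
        rule = SingleKernelRule(DiscrepancySpec.linf(), KernelSpec("gaussian", 0.5))
        run = abc_importance(TOY["model"], prior, q, TOY["spec"], rule,
                             TOY["y_obs"], m=500, seed=4)
        raw = np.array([
            np.exp(-(d ** 2) / (2 * 0.25)) * np.exp(prior.logpdf(t) - q.logpdf(t))
            for d, t in zip(run.discrepancies, run.thetas)])
        assert np.allclose(run.weights, raw / raw.sum())

    def test_importance_with_prior_proposal_reduces_to_rejection(self):
        run = abc_importance(TOY["model"], TOY["prior"], TOY["prior"], TOY["spec"],
                             TOY["rule"], TOY["y_obs"], m=2000, seed=5, mode="P")
        pos = run.weights > 0
        # all positive weights equal (uniform kernel, q = prior)
        assert np.allclose(run.weights[pos], run.weights[pos][0])

    def test_detailed_balance_flows(self):
        # empirical flow theta -> theta' equals theta' -> theta
        cfg = MCMCConfig(iterations=50_000, burn_in=2000,
                         propose=lambda th, rng: np.array([float(rng.integers(0, 2))]))
        run = abc_mcmc(TOY["model"], TOY["prior"], TOY["spec"], TOY["rule"],
                       TOY["y_obs"], cfg, seed=6)
        th = run.thetas[:, 0]
        f01 = np.mean((th[:-1] == 0) & (th[1:] == 1))
        f10 = np.mean((th[:-1] == 1) & (th[1:] == 0))
        se = np.sqrt(f01 * (1 - f01) / th.size)
        assert abs(f01 - f10) < 3 * se + 1e-3

    def test_zero_acceptance_diagnostics(self):
        rule = SingleKernelRule(DiscrepancySpec.linf(), KernelSpec("uniform", 0.0))
        with pytest.raises(ZeroAcceptanceError) as exc:
            abc_rejection(TOY["model"], TOY["prior"], TOY["spec"], rule,
                          np.array([0.5]), m=200, seed=7)
        assert exc.value.smallest_discrepancies is not None


class TestAcceptAllLimit:
    def test_rejection_h_inf_theta_marginal_is_prior(self):
        model = AR1Model(phi=0.5, sigma2=1.0, n=20, n_future=1)
        prior = UniformBoxPrior([-5.0], [5.0])
        spec = ar1_summary_spec(0.5, "s1")
        rule = SingleKernelRule(DiscrepancySpec.linf(), KernelSpec("uniform", np.inf))
        rng = np.random.default_rng(8)
        y = model.simulate_obs(np.array([1.0]), rng).y
        run = abc_rejection(model, prior, spec, rule, y, m=10_000, seed=9, mode="P")
        assert run.acceptance_rate == 1.0
        p = stats.kstest(run.thetas[:, 0], stats.uniform(-5, 10).cdf).pvalue
        assert p > 0.01

    def test_h_inf_predictive_is_prior_predictive(self):
        # the joint-simulation predictive at h = inf is the prior predictive
        model = AR1Model(phi=0.5, sigma2=1.0, n=20, n_future=1)
        prior = UniformBoxPrior([-2.0], [2.0])
        spec = ar1_summary_spec(0.5, "s1")
        rule = SingleKernelRule(DiscrepancySpec.linf(), KernelSpec("uniform", np.inf))
        rng = np.random.default_rng(10)
        y = model.simulate_obs(np.array([1.0]), rng).y
        run = abc_rejection(model, prior, spec, rule, y, m=6000, seed=11, mode="P")
        direct = []
        r2 = np.random.default_rng(12)
        for i in range(6000):
            sim = model.simulate_joint(prior.sample(r2), r2, r2)
            direct.append(sim.ytilde[0])
        p = stats.ks_2samp(run.ytilde[:, 0], np.asarray(direct)).pvalue
        assert p > 0.01


class TestMarginalizationConsistency:
    def test_theta_sample_path_equality(self):
        # the theta/z stream is untouched by switching prediction on: the
        # predictive run's theta marginal equals the plain posterior run's
        model = AR1Model(phi=0.5, sigma2=1.0, n=30, n_future=1)
        prior = UniformBoxPrior([-3.0], [3.0])
        spec = ar1_summary_spec(0.5, "s1")
        rule = SingleKernelRule(DiscrepancySpec.linf(), KernelSpec("uniform", 0.5))
        rng = np.random.default_rng(13)
        y = model.simulate_obs(np.array([1.0]), rng).y
        kw = dict(m=3000, seed=14)
        run_p = abc_rejection(model, prior, spec, rule, y, mode="P", **kw)
        run_post = abc_rejection(model, prior, spec, rule, y, mode="posterior", **kw)
        assert np.array_equal(run_p.thetas, run_post.thetas)
        assert np.array_equal(run_p.discrepancies, run_post.discrepancies)

    def test_theta_sample_path_equality_mcmc(self):
        model = AR1Model(phi=0.5, sigma2=1.0, n=30, n_future=1)
        prior = UniformBoxPrior([-3.0], [3.0])
        spec = ar1_summary_spec(0.5, "s1")
        rule = SingleKernelRule(DiscrepancySpec.linf(), KernelSpec("uniform", 0.5))
        rng = np.random.default_rng(15)
        y = model.simulate_obs(np.array([1.0]), rng).y
        cfg = MCMCConfig(iterations=4000, burn_in=200, proposal_scale=0.3,
                         init=np.array([1.0]))
        run_p = abc_mcmc(model, prior, spec, rule, y, cfg, seed=16, mode="P")
        run_post = abc_mcmc(model, prior, spec, rule, y, cfg, seed=16,
                            mode="posterior")
        assert np.array_equal(run_p.thetas, run_post.thetas)


class TestDeferredPrediction:
    def _mg1_run(self, seed, mode="P", store_states=False, m=8000):
        model = MG1Model(n=30, n_future=1)
        rng = np.random.default_rng(100)
        from predabc.mg1 import MG1Params, mg1_simulate

        y = mg1_simulate(MG1Params(4.0, 7.0, 0.15), 30, 0, rng).y
        prior = MG1Prior(y)
        spec = mg1_summary_spec("s0")
        rule = SingleKernelRule(DiscrepancySpec.identity(5), KernelSpec("uniform", 40.0))
        run = abc_rejection(model, prior, spec, rule, y, m=m, seed=seed,
                            mode=mode, store_states=store_states)
        return model, y, run

    def test_deferred_equals_joint_distribution(self):
        # simulate predictions after the fact from stored states: same law
        # as joint simulation (independent runs, two-sample KS)
        model, y, run_joint = self._mg1_run(17, mode="P")
        model2, y2, run_stored = self._mg1_run(18, mode="posterior",
                                               store_states=True)
        deferred = deferred_prediction(run_stored, model2, range(len(run_stored)),
                                       seed=19, use="state")
        p = stats.ks_2samp(run_joint.ytilde[:, 0], deferred[:, 0]).pvalue
        assert p > 0.01

    def test_empty_index_set(self):
        model, y, run = self._mg1_run(20, mode="posterior", store_states=True,
                                      m=2000)
        out = deferred_prediction(run, model, [], seed=21, use="state")
        assert out.size == 0

    def test_out_of_range_indices(self):
        model, y, run = self._mg1_run(22, mode="posterior", store_states=True,
                                      m=2000)
        with pytest.raises(IndexError):
            deferred_prediction(run, model, [len(run) + 5], seed=23, use="state")

    def test_zero_weight_records_do_not_change_estimate(self):
        # weighted predictive means agree whether or not zero-weight records
        # are simulated (they contribute nothing)
        model = ToyModel()
        prior = ToyPrior()
        rule = SingleKernelRule(DiscrepancySpec.linf(), KernelSpec("uniform", 0.0))
        run = abc_importance(model, prior, BiasedToyProposal(0.6),
                             toy_summary_spec(), rule, np.array([1.0]),
                             m=4000, seed=24, mode="P")
        pos = run.weights > 0
        est_all = np.nansum(run.weights * np.nan_to_num(run.ytilde[:, 0]))
        est_pos = np.sum(run.weights[pos] * run.ytilde[pos, 0])
        assert est_all == pytest.approx(est_pos)


class TestMCMCMechanics:
    def test_identical_state_proposal_always_accepted(self):
        # proposing the current theta with a fresh simulation that lands at
        # the same discrepancy gives acceptance probability one; with the
        # toy model at h=0 and s_y matched, any re-proposal of the same
        # theta that re-simulates z = s_y is accepted
        cfg = MCMCConfig(iterations=2000, burn_in=0,
                         propose=lambda th, rng: th.copy())
        run = abc_mcmc(TOY["model"], TOY["prior"], TOY["spec"], TOY["rule"],
                       TOY["y_obs"], cfg, seed=25)
        # acceptance rate equals the probability of re-simulating z = 1
        th = run.thetas[0, 0]
        p_match = 0.2 + 0.6 * th
        assert run.acceptance_rate == pytest.approx(p_match, abs=0.05)

    def test_rejected_proposal_repeats_whole_record(self):
        model = AR1Model(phi=0.5, sigma2=1.0, n=30, n_future=1)
        prior = UniformBoxPrior([-3.0], [3.0])
        spec = ar1_summary_spec(0.5, "s1")
        rule = SingleKernelRule(DiscrepancySpec.linf(), KernelSpec("uniform", 0.05))
        rng = np.random.default_rng(26)
        y = model.simulate_obs(np.array([1.0]), rng).y
        cfg = MCMCConfig(iterations=3000, burn_in=0, proposal_scale=0.5,
                         init=np.array([1.0]))
        run = abc_mcmc(model, prior, spec, rule, y, cfg, seed=27, mode="P")
        th = run.thetas[:, 0]
        yt = run.ytilde[:, 0]
        repeats = th[1:] == th[:-1]
        # wherever theta repeats (rejection), the prediction repeats too
        assert np.all(yt[1:][repeats] == yt[:-1][repeats])

    def test_initialization_failure_raises(self):
        rule = SingleKernelRule(DiscrepancySpec.linf(), KernelSpec("uniform", 0.0))
        cfg = MCMCConfig(iterations=100, burn_in=0, init_budget=200)
        with pytest.raises(RuntimeError, match="initial state"):
            abc_mcmc(TOY["model"], TOY["prior"], TOY["spec"], rule,
                     np.array([0.5]), cfg, seed=28)
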