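"""Hierarchical model and MCMC engine: correctness against independent
oracles, symmetries, determinism, diagnostics."""

import numpy as np
import pytest
from scipy.special import expit

import sparsemeta as sm
from sparsemeta.model import ModelState


def small_config(seed=0, iterations=60_000, burn_in=10_000, thin=2):
    return sm.McmcConfig(chains=3, iterations=iterations, burn_in=burn_in,
                         thin=thin, seed=seed)


def make_result(delta_draws, tau_draws=None, **extra):
    """Wrap raw chain draws in a PosteriorResult for summary/diagnostic tests."""
    chains, n = delta_draws.shape
    if tau_draws is None:
        tau_draws = np.abs(delta_draws) + 0.1
    k = 1
    draws = {
        "delta": delta_draws,
        "tau": tau_draws,
        "mu0": np.zeros_like(delta_draws),
        "mu": np.zeros((chains, n, k)),
        "d": np.zeros((chains, n, k)),
    }
    return sm.PosteriorResult(
        draws=draws,
        labels=("t1",),
        spec=sm.ModelSpec(sm.make_prior("c")),
        config=sm.McmcConfig(chains=chains, iterations=n, burn_in=0, thin=1),
        **extra,
    )


class TestLogJoint:
    def test_nonfinite_state_is_minus_inf(self, single_trial):
        spec = sm.ModelSpec(sm.make_prior("AU"))
        state = ModelState(np.inf, 0.0, 0.0, np.zeros(1), np.zeros(1))
        assert sm.log_joint(single_trial, spec, state) == -np.inf

    def test_arm_swap_symmetry(self, mmn):
        spec = sm.ModelSpec(sm.make_prior("dn"))
        rng = np.random.default_rng(5)
        for _ in range(10):
            state = ModelState(
                delta=rng.normal(),
                z=rng.normal(),
                mu0=rng.normal(),
                mu=rng.normal(size=mmn.k),
                d=rng.normal(size=mmn.k),
            )
            flipped = ModelState(-state.delta, state.z, state.mu0,
                                 state.mu.copy(), -state.d)
            a = sm.log_joint(mmn, spec, state)
            b = sm.log_joint(mmn.swap_arms(), spec, flipped)
            assert a == pytest.approx(b, rel=1e-12)

    def test_double_zero_trial_likelihood(self):
        # (0/5, 0/5) at delta_i = 0, mu_i = -10: each of the ten subjects
        # contributes log(1 - expit(-10)), about -4.5e-5 apiece
        ds = sm.MetaAnalysisDataset((sm.TrialRecord("t", 0, 5, 0, 5),))
        spec = sm.ModelSpec(sm.make_prior("c"))
        state = ModelState(0.0, 0.0, -10.0, np.array([-10.0]), np.array([0.0]))
        with_lik = sm.log_joint(ds, spec, state)
        without = sm.log_joint(ds, spec, state, include_likelihood=False)
        assert with_lik - without == pytest.approx(10 * np.log1p(-expit(-10)),
                                                   rel=1e-9)


class TestQuadratureOracle:
    def test_posterior_moments_match_quadrature(self, single_trial):
        """k=1 with tau fixed: MCMC mean/SD of delta vs 2-D quadrature.

        delta and mu0 are integrated out analytically (normal-normal),
        leaving a 2-D posterior over (mu_1, d_1) evaluated on a grid.
        """
        tau = 0.5
        trial = single_trial.trials[0]
        v_d = tau**2 + 100.0  # prior var of d_1 with delta integrated out
        v_m = 100.0 + 1.0e6  # prior var of mu_1 with mu0 integrated out
        mu_g = np.linspace(-15, 15, 601)
        d_g = np.linspace(-20, 20, 601)
        M, D = np.meshgrid(mu_g, d_g, indexing="ij")
        et, ec = M + 0.5 * D, M - 0.5 * D
        loglik = (
            trial.r_t * np.log(expit(et))
            + (trial.n_t - trial.r_t) * np.log(expit(-et))
            + trial.r_c * np.log(expit(ec))
            + (trial.n_c - trial.r_c) * np.log(expit(-ec))
        )
        logpost = loglik - D**2 / (2 * v_d) - M**2 / (2 * v_m)
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        e_d1 = float((w * D).sum())
        v_d1 = float((w * (D - e_d1) ** 2).sum())
        shrink = 100.0 / (100.0 + tau**2)
        oracle_mean = shrink * e_d1
        oracle_sd = np.sqrt(100.0 * tau**2 / (100.0 + tau**2)
                            + shrink**2 * v_d1)

        res = sm.fit(
            single_trial,
            sm.ModelSpec(sm.fixed_tau(tau)),
            small_config(seed=3, iterations=150_000, burn_in=20_000, thin=5),
            check_convergence=False,
        )
        x = res.flat("delta")
        ess = 3 * 26_000 / 50  # conservative ESS guess for the MC-SE
        mc_se_mean = x.std() / np.sqrt(ess)
        assert x.mean() == pytest.approx(oracle_mean, abs=3 * mc_se_mean)
        assert x.std() == pytest.approx(oracle_sd, rel=0.05)


class TestPriorRecovery:
    @pytest.mark.parametrize("pid", ["dn", "c", "AU"])
    def test_tau_marginal_reproduces_prior(self, single_trial, pid):
        """With the binomial terms switched off the tau marginal is the
        heterogeneity prior itself."""
        prior = sm.make_prior(pid)
        res = sm.fit(
            single_trial,
            sm.ModelSpec(prior),
            small_config(seed=11, iterations=120_000, burn_in=20_000, thin=4),
            include_likelihood=False,
            check_convergence=False,
        )
        t = res.flat("tau")
        for p in (0.25, 0.5, 0.75):
            # compare on the probability scale: empirical CDF at the
            # analytic quantile, generous MC margin for RW autocorrelation
            assert np.mean(t <= prior.tau_quantile(p)) == pytest.approx(
                p, abs=0.03
            )


class TestFitBehaviour:
    def test_seeded_determinism(self, mmn):
        spec = sm.ModelSpec(sm.make_prior("dn"))
        cfg = small_config(seed=42, iterations=6000, burn_in=1000, thin=1)
        a = sm.fit(mmn, spec, cfg, check_convergence=False)
        b = sm.fit(mmn, spec, cfg, check_convergence=False)
        assert np.array_equal(a.draws["delta"], b.draws["delta"])
        assert np.array_equal(a.draws["tau"], b.draws["tau"])
        c = sm.fit(mmn, spec, small_config(seed=43, iterations=6000,
                                           burn_in=1000, thin=1),
                   check_convergence=False)
        assert not np.array_equal(a.draws["delta"], c.draws["delta"])

    def test_arm_swap_negates_delta(self, gbs):
        spec = sm.ModelSpec(sm.make_prior("dn"))
        cfg = small_config(seed=9)
        med = sm.summarize(sm.fit(gbs, spec, cfg))["delta"]["median"]
        med_sw = sm.summarize(sm.fit(gbs.swap_arms(), spec, cfg))["delta"]["median"]
        assert med == pytest.approx(-med_sw, abs=0.05)

    def test_parameter_recovery_low_heterogeneity(self):
        """k=6 informative trials, true logOR 0.5, tau ~ 0: the average
        posterior median under the log-uniform prior lands near truth."""
        scenario = sm.Scenario(k=6, n_low=40, n_high=50, pi_c=0.3,
                               tau=0.01, delta=0.5, n_reps=100, seed=77)
        spec = sm.ModelSpec(sm.make_prior("AU"))
        medians = []
        for rep in range(scenario.n_reps):
            ds = sm.simulate_dataset(scenario, rep)
            res = sm.fit(ds, spec,
                         sm.McmcConfig(chains=2, iterations=8000, burn_in=2000,
                                       thin=1, seed=rep),
                         check_convergence=False)
            medians.append(np.median(res.flat("delta")))
        assert np.mean(medians) == pytest.approx(0.5, abs=0.15)


class TestSummarize:
    def test_order_statistics(self):
        x = np.arange(1, 1001) / 100.0
        res = make_result(x[None, :].repeat(2, axis=0))
        s = sm.summarize(res)["delta"]
        assert s["median"] == pytest.approx(5.005)
        assert s["cri_low"] == pytest.approx(0.26, abs=0.01)
        assert s["cri_high"] == pytest.approx(9.76, abs=0.01)
        assert s["p_positive"] == 1.0

    def test_requires_enough_draws(self):
        res = make_result(np.zeros((2, 100)))
        with pytest.raises(ValueError, match="1000"):
            sm.summarize(res)

    def test_beneficial_side_follows_median(self):
        rng = np.random.default_rng(0)
        neg = make_result(rng.normal(-2, 1, size=(2, 2000)))
        pos = make_result(rng.normal(2, 1, size=(2, 2000)))
        assert sm.beneficial_side_probability(neg) == pytest.approx(
            np.mean(neg.flat("delta") < 0))
        assert sm.beneficial_side_probability(pos) == pytest.approx(
            np.mean(pos.flat("delta") > 0))


class TestDiagnostics:
    def test_iid_chains_have_unit_rhat(self):
        rng = np.random.default_rng(1)
        res = make_result(rng.normal(size=(3, 2000)))
        d = sm.diagnostics(res)
        assert 0.99 < d.loc["delta", "rhat"] < 1.01
        assert d.loc["delta", "ess_bulk"] > 3000

    def test_autocorrelated_chains_have_small_ess(self):
        rng = np.random.default_rng(2)
        rho, n = 0.99, 4000
        chains = np.empty((3, n))
        for c in range(3):
            e = rng.normal(size=n) * np.sqrt(1 - rho**2)
            x = np.empty(n)
            x[0] = rng.normal()
            for t in range(1, n):
                x[t] = rho * x[t - 1] + e[t]
            chains[c] = x
        res = make_result(chains)
        d = sm.diagnostics(res)
        assert d.loc["delta", "ess_bulk"] < 0.1 * 3 * n
        assert d.loc["delta", "lag1_autocorr"] > 0.9

    def test_constant_chains_flagged(self):
        res = make_result(np.ones((2, 1500)))
        d = sm.diagnostics(res)
        assert np.isnan(d.loc["delta", "rhat"]) or d.loc["delta", "rhat"] > 1.05

    def test_single_chain_rejected(self):
        res = make_result(np.random.default_rng(3).normal(size=(1, 1500)))
        with pytest.raises(ValueError, match="two chains"):
            sm.diagnostics(res)
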