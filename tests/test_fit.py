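"""DE-MCMC machinery: priors, proposal, acceptance rule, sampler checks."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.special import expit

from conftest import make_trials
from trdm import fast_timer_agent
from trdm.fit import (PriorSpec, Schedule, de_propose, default_priors,
                      demcmc_sample, mh_accept, prior_logpdf, rhat, run_demcmc)
from trdm.likelihood import PARAM_NAMES, ModelParams
from trdm.wald import DriftLinkCoefs


class TestPriors:
    def test_default_tables(self):
        rdm = {p.name: p for p in default_priors("RDM")}
        trdm = {p.name: p for p in default_priors("TRDM")}
        assert set(rdm) == set(PARAM_NAMES["RDM"])
        assert set(trdm) == set(PARAM_NAMES["TRDM"])
        assert rdm["omega"].family == "IL" and rdm["omega"].scale == 1.4
        assert trdm["gamma"].location == -1.0
        assert trdm["rho_t"].family == "LN" and trdm["rho_t"].location == 1.56

    def test_prior_medians(self):
        # IL(0, .) has median logistic(0) = 0.5; LN(1.56, .) has median e^1.56
        rng = np.random.default_rng(0)
        omega_draws = expit(rng.normal(0.0, 1.4, 200_000))
        assert np.median(omega_draws) == pytest.approx(0.5, abs=0.01)
        drift_draws = np.exp(rng.normal(1.56, 1.5, 200_000))
        assert np.median(drift_draws) == pytest.approx(np.exp(1.56), rel=0.02)

    def test_prior_logpdf_matches_lognorm(self):
        # an LN-only model parameterisation cross-checked against scipy
        params = ModelParams(omega=0.5, t0=0.2, coefs=DriftLinkCoefs(2, 3, 1),
                             eta_c=0.8, kind="RDM")
        lp = prior_logpdf(params)
        expected = 0.0
        for name, theta in zip(params.free_names, params.to_vector()):
            if name in ("omega", "t0"):
                z = np.log(theta / (1 - theta))
                expected += stats.norm.logpdf(z, 0.0, 1.4) - np.log(theta * (1 - theta))
            else:
                expected += stats.lognorm.logpdf(theta, s=1.5, scale=np.exp(1.56))
        assert lp == pytest.approx(expected, rel=1e-10)

    def test_prior_density_integrates_to_one(self):
        spec = PriorSpec("gamma", "IL", -1.0, 1.0)

        def dens(theta):
            z = np.log(theta / (1 - theta))
            return (stats.norm.pdf(z, spec.location, spec.scale)
                    / (theta * (1 - theta)))

        total, _ = quad(dens, 1e-12, 1 - 1e-12, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_out_of_support_is_minus_inf(self):
        priors = default_priors("RDM")
        params = ModelParams(omega=0.5, t0=1.5, coefs=DriftLinkCoefs(1, 1, 1),
                             eta_c=1.0, kind="RDM")
        # t0 = 1.5 is outside the (0, 1) support implied by its IL prior
        assert prior_logpdf(params, priors) == -np.inf

    def test_missing_prior_rejected(self):
        params = ModelParams(omega=0.5, t0=0.1, coefs=DriftLinkCoefs(1, 1, 1),
                             eta_c=1.0, kind="RDM")
        with pytest.raises(ValueError):
            prior_logpdf(params, default_priors("RDM")[:-1])


class TestDePropose:
    def test_null_difference_leaves_only_jitter(self):
        states = np.tile([1.0, -2.0, 0.5], (5, 1))
        rng = np.random.default_rng(1)
        prop = de_propose(states, 0, rng)
        assert np.all(np.abs(prop - states[0]) <= 1e-4)

    def test_mean_displacement_zero(self):
        rng = np.random.default_rng(2)
        states = rng.normal(size=(20, 4))
        disp = np.mean([de_propose(states, 3, rng) - states[3]
                        for _ in range(4000)], axis=0)
        assert np.all(np.abs(disp) < 0.05)

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError):
            de_propose(np.zeros((2, 3)), 0, np.random.default_rng(0))


class TestMhAccept:
    def test_uphill_always_accepted(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            state, ok = mh_accept(0.0, 1.0, -10.0, -5.0, rng)
            assert ok and state == 1.0

    def test_same_point_always_accepted(self):
        rng = np.random.default_rng(4)
        state, ok = mh_accept(2.0, 2.0, -7.0, -7.0, rng)
        assert ok

    def test_empirical_acceptance_rate(self):
        rng = np.random.default_rng(5)
        r = 0.3
        n = 30_000
        accepted = sum(mh_accept(0, 1, 0.0, np.log(r), rng)[1] for _ in range(n))
        se = np.sqrt(r * (1 - r) / n)
        assert abs(accepted / n - r) < 3 * se


class TestSamplerOnConjugateTarget:
    """Normal likelihood with known variance + normal prior on the mean:
    the posterior is available in closed form."""

    @staticmethod
    def _run(seed):
        rng_data = np.random.default_rng(100)
        data = rng_data.normal(1.3, 0.8, size=50)
        s2, mu0, tau2 = 0.8**2, 0.0, 2.0**2
        n = len(data)
        post_var = 1.0 / (n / s2 + 1.0 / tau2)
        post_mean = post_var * (data.sum() / s2 + mu0 / tau2)

        def logpost(z):
            mu = z[:, 0]
            ll = -0.5 * ((data[None, :] - mu[:, None]) ** 2 / s2).sum(axis=1)
            lp = -0.5 * (mu - mu0) ** 2 / tau2
            return ll + lp

        rng = np.random.default_rng(seed)
        init = rng.normal(mu0, np.sqrt(tau2), size=(10, 1))
        hist, _ = demcmc_sample(logpost, init, Schedule(burn=200, samples=500), rng)
        return hist[:, 200:, 0], post_mean, np.sqrt(post_var)

    def test_posterior_moments_within_two_percent(self):
        draws, mean, sd = self._run(seed=6)
        pooled = draws.ravel()
        assert pooled.mean() == pytest.approx(mean, rel=0.02)
        assert pooled.std() == pytest.approx(sd, rel=0.05)

    def test_quantiles_match_analytic(self):
        draws, mean, sd = self._run(seed=7)
        pooled = draws.ravel()
        qs = np.arange(0.1, 0.91, 0.1)
        analytic = stats.norm.ppf(qs, mean, sd)
        sampled = np.quantile(pooled, qs)
        # 2% tolerance on the (mean-magnitude) scale of the target
        assert np.all(np.abs(sampled - analytic) < 0.02 * max(abs(mean), 1.0)
                      + 0.05 * sd)

    def test_chains_exchangeable_across_seeds(self):
        # two independently seeded runs target the same posterior; their
        # pooled quantiles agree to within a fraction of the posterior SD
        a, _, sd = self._run(seed=8)
        b, _, _ = self._run(seed=9)
        qs = np.arange(0.1, 0.91, 0.1)
        assert np.all(np.abs(np.quantile(a.ravel(), qs)
                             - np.quantile(b.ravel(), qs)) < 0.2 * sd)

    def test_rhat_near_one(self):
        draws, _, _ = self._run(seed=10)
        assert rhat(draws) < 1.1


class TestRunDemcmc:
    @pytest.fixture(scope="class")
    def small_fit(self):
        trials = make_trials(fast_timer_agent(), 400, seed=55)
        return run_demcmc(trials, "RDM", schedule=Schedule(burn=30, samples=50),
                          seed=55), trials

    def test_chain_count_follows_ten_k_rule(self, small_fit):
        post, _ = small_fit
        assert post.samples.shape[0] == 60  # 10 x 6 free parameters
        assert post.samples.shape[1] == 80
        assert post.param_names == PARAM_NAMES["RDM"]

    def test_natural_scale_supports_respected(self, small_fit):
        post, _ = small_fit
        pooled = post.samples.reshape(-1, 6)
        by = dict(zip(post.param_names, pooled.T))
        assert np.all((by["omega"] > 0) & (by["omega"] < 1))
        assert np.all((by["t0"] > 0) & (by["t0"] < 1))
        for name in ("v0", "vd", "vs", "eta_c"):
            assert np.all(by[name] > 0)

    def test_deterministic_for_fixed_seed(self):
        trials = make_trials(fast_timer_agent(), 150, seed=56)
        kw = dict(schedule=Schedule(burn=10, samples=15), seed=7)
        a = run_demcmc(trials, "RDM", **kw)
        b = run_demcmc(trials, "RDM", **kw)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.loglik, b.loglik)

    def test_best_vector_attains_max_loglik(self, small_fit):
        post, trials = small_fit
        from trdm.likelihood import dataset_loglik
        best = ModelParams.from_vector(post.best_vector(), "RDM")
        assert dataset_loglik(trials, best) == pytest.approx(post.max_loglik(),
                                                             rel=1e-9)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            run_demcmc(None, "DDM")
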