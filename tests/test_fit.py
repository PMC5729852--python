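"""Estimator correctness: quadrature oracles, likelihood arithmetic,
missing-data policies, chain invariance and the shared biometric kernel."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import twinirt as t
from twinirt._kernel import AceKernel
from twinirt.fit import LatentState, PriorSpec, _validate_obs
from twinirt.model import AceMParams
from twinirt.simulate import SCENARIO_PARAMS


def _kernel_priors():
    return PriorSpec().to_kernel()


class TestAugmentedLogLikelihood:
    def test_hand_computed_single_mz_family(self):
        params = AceMParams(mu=0.2, beta1m=0.3, beta0a=np.log(0.3), beta0c=np.log(0.2),
                            beta0e=np.log(0.5))
        state = LatentState(theta=np.array([[0.5, -0.1]]), family_effect=np.array([0.4]))
        bank = t.ItemBank(difficulty=[0.7])
        resp = np.array([[[1.0], [0.0]]])
        got = t.log_likelihood([True], [1.0], state, params, responses=resp, bank=bank)
        mean = 0.2 + 0.3
        expected = scipy.stats.norm.logpdf(0.4, mean, np.sqrt(0.5))
        expected += scipy.stats.norm.logpdf(0.5, 0.4, np.sqrt(0.5))
        expected += scipy.stats.norm.logpdf(-0.1, 0.4, np.sqrt(0.5))
        p1 = 1 / (1 + np.exp(-(0.5 - 0.7)))
        p2 = 1 / (1 + np.exp(-(-0.1 - 0.7)))
        expected += np.log(p1) + np.log(1 - p2)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_no_observed_items_reduces_to_hierarchy(self):
        params = SCENARIO_PARAMS
        state = LatentState(theta=np.array([[0.1, 0.2]]), family_effect=np.array([0.0]))
        bank = t.ItemBank(difficulty=[0.0, 1.0])
        nan_resp = np.full((1, 2, 2), np.nan)
        with_items = t.log_likelihood([True], [0.0], state, params, responses=nan_resp, bank=bank)
        without = t.log_likelihood([True], [0.0], state, params)
        assert with_items == pytest.approx(without)

    def test_saturated_items_contribute_nothing(self):
        params = SCENARIO_PARAMS
        state = LatentState(theta=np.array([[40.0, 40.0]]), family_effect=np.array([0.0]))
        bank = t.ItemBank(difficulty=[0.0])
        resp = np.ones((1, 2, 1))
        with_items = t.log_likelihood([True], [0.0], state, params, responses=resp, bank=bank)
        without = t.log_likelihood([True], [0.0], state, params)
        assert with_items == pytest.approx(without, abs=1e-12)

    def test_collapsed_matches_augmented_mz_by_quadrature(self):
        """Integrating the augmented density over the MZ familial effect
        recovers the collapsed bivariate-normal pair likelihood."""
        params = AceMParams(mu=0.1, beta1m=-0.4, beta0a=np.log(0.3), beta1a=0.2,
                            beta0c=np.log(0.3), beta1c=-0.1, beta0e=np.log(0.4), beta1e=0.1)
        theta = np.array([[0.6, -0.3]])
        kern = AceKernel(theta=theta, mz=[True], moderator=[1.0],
                         priors=_kernel_priors(), rng=np.random.default_rng(0))
        collapsed = float(kern.pair_loglik(params.to_array())[0])
        f_grid = np.linspace(-8, 8, 4001)
        vals = [
            t.log_likelihood([True], [1.0],
                             LatentState(theta=theta, family_effect=np.array([f])), params)
            for f in f_grid
        ]
        marginal = np.log(np.trapezoid(np.exp(vals), f_grid))
        assert collapsed == pytest.approx(marginal, abs=1e-6)

    def test_collapsed_matches_augmented_dz_by_monte_carlo(self):
        """Averaging the augmented DZ density over prior draws of (C, A1, A2)
        recovers the collapsed pair likelihood within Monte-Carlo error."""
        params = AceMParams(mu=0.0, beta1m=0.0, beta0a=np.log(0.25), beta0c=np.log(0.25),
                            beta0e=np.log(0.5))
        theta = np.array([[0.4, -0.2]])
        kern = AceKernel(theta=theta, mz=[False], moderator=[0.0],
                         priors=_kernel_priors(), rng=np.random.default_rng(0))
        collapsed = float(kern.pair_loglik(params.to_array())[0])
        rng = np.random.default_rng(7)
        n = 400_000
        c = rng.normal(0.0, np.sqrt(0.25), n)
        a1 = rng.standard_normal(n)
        a2 = rng.standard_normal((n, 2))
        w = np.sqrt(0.5)
        mean = c[:, None] + np.sqrt(0.25) * (w * a1[:, None] + w * a2)
        dens = scipy.stats.norm.pdf(theta[0, 0], mean[:, 0], np.sqrt(0.5)) * scipy.stats.norm.pdf(
            theta[0, 1], mean[:, 1], np.sqrt(0.5)
        )
        assert collapsed == pytest.approx(np.log(dens.mean()), abs=0.01)

    def test_requires_dz_genetic_state(self):
        state = LatentState(theta=np.zeros((1, 2)), family_effect=np.zeros(1))
        with pytest.raises(ValueError):
            t.log_likelihood([False], [0.0], state, SCENARIO_PARAMS)


class TestQuadratureOracle:
    def test_posterior_mean_of_mu_matches_grid_integration(self):
        """On a tiny instance (2 families x 2 items) with the variance
        coefficients held at truth, the MCMC posterior of mu must agree with
        deterministic numerical integration over (mu, theta)."""
        params = AceMParams(mu=0.3, beta1m=0.0, beta0a=np.log(0.25), beta0c=np.log(0.25),
                            beta0e=np.log(0.5))
        bank = t.ItemBank(difficulty=[-0.5, 0.8])
        mz = np.array([True, False])
        M = np.zeros(2)
        resp = np.array(
            [[[1.0, 0.0], [1.0, 1.0]],
             [[0.0, 0.0], [1.0, 0.0]]]
        )
        priors = PriorSpec()

        # --- oracle: p(mu | Y) on a grid, theta integrated per family ------
        mu_grid = np.linspace(-4, 4, 161)
        th = np.linspace(-7, 7, 141)
        t1g, t2g = np.meshgrid(th, th, indexing="ij")

        def family_marginal(mu, fam):
            mean = np.array([mu, mu])
            _, cov = t.twin_trait_covariance(
                AceMParams(mu=mu, beta0a=np.log(0.25), beta0c=np.log(0.25), beta0e=np.log(0.5)),
                0.0, "MZ" if mz[fam] else "DZ")
            dens = scipy.stats.multivariate_normal.pdf(
                np.dstack([t1g, t2g]), mean=mean, cov=cov)
            for j, grid in ((0, t1g), (1, t2g)):
                for k in range(2):
                    p = 1 / (1 + np.exp(-(grid - bank.difficulty[k])))
                    dens = dens * np.where(resp[fam, j, k] == 1.0, p, 1 - p)
            return np.trapezoid(np.trapezoid(dens, th, axis=1), th)

        post = np.array(
            [
                scipy.stats.norm.pdf(mu, priors.mu_loc, priors.mu_scale)
                * family_marginal(mu, 0)
                * family_marginal(mu, 1)
                for mu in mu_grid
            ]
        )
        post /= np.trapezoid(post, mu_grid)
        oracle_mean = np.trapezoid(mu_grid * post, mu_grid)
        oracle_sd = np.sqrt(np.trapezoid((mu_grid - oracle_mean) ** 2 * post, mu_grid))

        # --- MCMC on the same slice ---------------------------------------
        kern = AceKernel(
            theta=np.zeros((2, 2)), mz=mz, moderator=M, priors=priors.to_kernel(),
            rng=np.random.default_rng(3), responses=resp,
            difficulty=bank.difficulty, discrimination=bank.discrimination,
            sample_varcoefs=False,
        )
        kern.params = params.to_array()
        for _ in range(2000):
            kern.step(adapt=True)
        kern.finalize_adaptation()
        draws = np.empty(60_000)
        for i in range(draws.size):
            kern.step(adapt=False)
            draws[i] = kern.params[0]
        assert draws.mean() == pytest.approx(oracle_mean, abs=0.02 + 0.02 * abs(oracle_mean))
        assert draws.std() == pytest.approx(oracle_sd, rel=0.05)


class TestValidationAndPolicies:
    def _obs(self, tiny_dataset):
        return tiny_dataset.obs.copy()

    def test_all_missing_item_column_named(self, tiny_dataset):
        obs = self._obs(tiny_dataset)
        obs["item_3"] = np.nan
        with pytest.raises(ValueError, match="item_3"):
            t.IrtAceModel(mcmc=t.McmcConfig.quick()).fit(obs, item_bank=tiny_dataset.bank)

    def test_single_zygosity_rejected(self, tiny_dataset):
        obs = self._obs(tiny_dataset)
        obs["zygosity"] = "MZ"
        with pytest.raises(ValueError, match="MZ and DZ"):
            _validate_obs(obs, None)

    def test_individual_moderator_rejected(self, tiny_dataset):
        obs = self._obs(tiny_dataset)
        obs.loc[0, "moderator"] = 1 - obs.loc[0, "moderator"]
        with pytest.raises(ValueError, match="family-level"):
            _validate_obs(obs, None)

    def test_incomplete_pair_rejected(self, tiny_dataset):
        obs = self._obs(tiny_dataset).iloc[1:]
        with pytest.raises(ValueError, match="two twins"):
            _validate_obs(obs, None)

    def test_bad_response_codes_rejected(self, tiny_dataset):
        obs = self._obs(tiny_dataset)
        obs.loc[0, "item_1"] = 2.0
        with pytest.raises(ValueError, match="0, 1 or missing"):
            _validate_obs(obs, [c for c in obs if c.startswith("item_")])

    def test_moderator_policies(self, tiny_dataset):
        obs = self._obs(tiny_dataset)
        fams = obs["family_id"].unique()
        half = fams[: len(fams) // 2]
        obs.loc[obs["family_id"].isin(half), "moderator"] = np.nan
        kept = t.apply_moderator_policy(obs, "impute")
        dropped = t.apply_moderator_policy(obs, "complete-cases")
        assert kept["family_id"].nunique() == len(fams)
        assert dropped["family_id"].nunique() == len(fams) - len(half)
        with pytest.raises(ValueError):
            t.apply_moderator_policy(obs, "listwise")

    def test_imputation_fit_retains_all_families(self, tiny_dataset):
        obs = self._obs(tiny_dataset)
        fams = obs["family_id"].unique()
        obs.loc[obs["family_id"].isin(fams[::2]), "moderator"] = np.nan
        est = t.IrtAceModel(mcmc=t.McmcConfig.quick(seed=1)).fit(obs, item_bank=tiny_dataset.bank)
        assert est.n_pairs_ == len(fams)
        # moderator probabilities were actually sampled
        assert 0.0 < est.posterior_.mean("pi_dz") < 1.0

    def test_bank_size_mismatch(self, tiny_dataset):
        small_bank = t.ItemBank(difficulty=[0.0])
        with pytest.raises(ValueError, match="item bank"):
            t.IrtAceModel(mcmc=t.McmcConfig.quick()).fit(
                tiny_dataset.obs, item_bank=small_bank)


class TestEstimatorBehaviour:
    def test_sklearn_params_roundtrip(self):
        est = t.IrtAceModel(random_state=3)
        params = est.get_params()
        assert params["random_state"] == 3
        est.set_params(missing_moderator="complete-cases")
        assert est.missing_moderator == "complete-cases"

    def test_fit_reproducible_given_seed(self, tiny_dataset):
        kw = dict(mcmc=t.McmcConfig.quick(seed=11))
        a = t.IrtAceModel(**kw).fit(tiny_dataset.obs, item_bank=tiny_dataset.bank)
        b = t.IrtAceModel(**kw).fit(tiny_dataset.obs, item_bank=tiny_dataset.bank)
        for name in a.posterior_.names:
            assert np.array_equal(a.posterior_.draws[name], b.posterior_.draws[name])

    def test_chain_invariance_across_seeds(self, small_dataset):
        """Two independently seeded runs agree in posterior means within
        Monte-Carlo error."""
        mk = lambda s: t.IrtAceModel(
            mcmc=t.McmcConfig(n_adapt=300, n_burnin=300, n_keep=1200, seed=s)
        ).fit(small_dataset.obs, item_bank=small_dataset.bank)
        a, b = mk(1), mk(2)
        assert a.posterior_.mean("mu") == pytest.approx(b.posterior_.mean("mu"), abs=0.06)
        assert a.posterior_.mean("beta1m") == pytest.approx(b.posterior_.mean("beta1m"), abs=0.1)
        assert a.posterior_.mean("beta0e") == pytest.approx(b.posterior_.mean("beta0e"), abs=0.25)

    def test_summary_and_posterior_shapes(self, tiny_dataset):
        est = t.IrtAceModel(mcmc=t.McmcConfig(n_adapt=50, n_burnin=50, n_keep=100, n_chains=2, seed=0))
        est.fit(tiny_dataset.obs, item_bank=tiny_dataset.bank)
        assert est.posterior_.n_chains == 2
        assert est.posterior_.n_draws == 100
        for name in list(AceMParams.names()) + ["pi_mz", "pi_dz"]:
            assert name in est.posterior_.names
        assert {"exp_beta0a", "h2"} <= set(est.summary_.index)
        p = est.params_posterior_mean()
        assert isinstance(p, AceMParams)
        assert 0.0 < est.heritability_posterior_mean() < 1.0

    def test_posterior_frame_roundtrip(self, tiny_dataset):
        est = t.IrtAceModel(mcmc=t.McmcConfig.quick(seed=5)).fit(
            tiny_dataset.obs, item_bank=tiny_dataset.bank)
        again = t.PosteriorSamples.from_frame(est.posterior_.to_frame())
        for name in est.posterior_.names:
            assert np.allclose(again.draws[name], est.posterior_.draws[name])

    def test_store_theta(self, tiny_dataset):
        est = t.IrtAceModel(mcmc=t.McmcConfig.quick(seed=5), store_theta=True, theta_thin=100)
        est.fit(tiny_dataset.obs, item_bank=tiny_dataset.bank)
        assert est.posterior_.theta is not None
        assert est.posterior_.theta.shape[-2:] == (est.n_pairs_, 2)

    def test_variance_transforms_positive(self, tiny_dataset):
        est = t.IrtAceModel(mcmc=t.McmcConfig.quick(seed=5)).fit(
            tiny_dataset.obs, item_bank=tiny_dataset.bank)
        for name, arr in est.posterior_.derived().items():
            assert np.all(arr > 0), name


class TestSharedBiometricKernel:
    def test_both_models_use_one_kernel_code_path(self, tiny_dataset):
        irt = t.IrtAceModel(mcmc=t.McmcConfig.quick(seed=1))
        ss = t.SumScoreAceModel(mcmc=t.McmcConfig.quick(seed=1))
        fam, mz, M, resp = irt._prepare(tiny_dataset.obs, tiny_dataset.bank)
        k_irt = irt._make_kernel(mz, M, resp, PriorSpec(), np.random.default_rng(0))
        fam, mz, M, phen = ss._prepare(tiny_dataset.obs, None)
        k_ss = ss._make_kernel(mz, M, phen, PriorSpec(), np.random.default_rng(0))
        assert type(k_irt) is type(k_ss) is AceKernel

    def test_identical_phenotypes_identical_posterior_target(self, tiny_dataset):
        """The biometric core gives the same per-family log-likelihood no
        matter which estimator built the kernel."""
        ss = t.SumScoreAceModel(mcmc=t.McmcConfig.quick(seed=1))
        _, mz, M, phen = ss._prepare(tiny_dataset.obs, None)
        k1 = AceKernel(theta=phen, mz=mz, moderator=M, priors=PriorSpec().to_kernel(),
                       rng=np.random.default_rng(0))
        k2 = AceKernel(theta=phen, mz=mz, moderator=M, priors=PriorSpec().to_kernel(),
                       rng=np.random.default_rng(99), responses=None)
        p = SCENARIO_PARAMS.to_array()
        assert np.allclose(k1.pair_loglik(p), k2.pair_loglik(p))
        # and a kernel with an item layer shares the identical biometric term
        irt = t.IrtAceModel(mcmc=t.McmcConfig.quick(seed=1))
        _, mz2, M2, resp = irt._prepare(tiny_dataset.obs, tiny_dataset.bank)
        k3 = irt._make_kernel(mz2, M2, resp, PriorSpec(), np.random.default_rng(0))
        k3.theta = np.array(phen)
        assert np.allclose(k3.pair_loglik(p), k1.pair_loglik(p))
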