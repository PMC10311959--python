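import numpy as np
import pytest

from speedirt import (
    ConvergenceRules,
    MCMCConfig,
    ModelSpec,
    PriorConfig,
    code_missingness,
    fit_model,
    run_mcmc,
)
from speedirt.data_io import design_matrix
from speedirt.sampler import initialize_chain, sample_latent_covariance


class TestMCMCConfig:
    def test_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            MCMCConfig(n_chains=3, n_posterior_total=100)

    def test_zero_posterior_draws_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_posterior_total=0)

    def test_keep_per_chain_bookkeeping(self):
        cfg = MCMCConfig(n_chains=3, n_posterior_total=3)
        assert cfg.n_keep_per_chain == 1

    def test_escalation_preset(self):
        cfg = MCMCConfig(n_burnin=25_000, escalated_burnin=100_000)
        assert cfg.escalated().n_burnin == 100_000


class TestInitializeChain:
    def _spec(self):
        return ModelSpec(model_id=2, K=5)

    def test_deterministic_given_seed_and_chain(self):
        cfg = MCMCConfig(seed=3, n_posterior_total=3, n_chains=3)
        a = initialize_chain(self._spec(), 10, cfg, chain_id=1)
        b = initialize_chain(self._spec(), 10, cfg, chain_id=1)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.b, b.b)
        assert a.tau1 == b.tau1 and a.sigma_b == b.sigma_b

    def test_chains_are_overdispersed(self):
        cfg = MCMCConfig(seed=3, n_posterior_total=3, n_chains=3)
        a = initialize_chain(self._spec(), 10, cfg, chain_id=1)
        b = initialize_chain(self._spec(), 10, cfg, chain_id=2)
        assert not np.array_equal(a.b, b.b)

    def test_zero_dispersion_collapses_to_prior_means(self):
        cfg = MCMCConfig(seed=3, n_posterior_total=3, n_chains=3, init_dispersion=0.0)
        for chain_id in (1, 2, 3):
            s = initialize_chain(self._spec(), 10, cfg, chain_id=chain_id)
            np.testing.assert_array_equal(s.b, 0.0)
            assert s.tau1 == 0.0 and s.sigma_b == 1.0
            np.testing.assert_array_equal(s.Sigma, np.eye(2))


class TestRunMcmc:
    def test_retained_draw_bookkeeping(self, small_cohort):
        data, ind = small_cohort
        cfg = MCMCConfig(n_chains=3, n_adapt=5, n_burnin=5, n_posterior_total=3, seed=1)
        draws = run_mcmc(data.responses, ind, None, ModelSpec(1, K=5), cfg)
        assert draws.get("tau1").shape == (3, 1)

    def test_bit_identical_reproducibility(self, small_cohort):
        data, ind = small_cohort
        cfg = MCMCConfig(n_chains=2, n_adapt=30, n_burnin=30, n_posterior_total=100, seed=9)
        a = run_mcmc(data.responses, ind, None, ModelSpec(1, K=5), cfg)
        b = run_mcmc(data.responses, ind, None, ModelSpec(1, K=5), cfg)
        for name in a.parameter_names():
            np.testing.assert_array_equal(a.get(name), b.get(name))

    def test_design_mismatch_errors(self, small_cohort):
        data, ind = small_cohort
        cfg = MCMCConfig(n_chains=2, n_adapt=5, n_burnin=5, n_posterior_total=2, seed=1)
        with pytest.raises(ValueError, match="design columns"):
            run_mcmc(data.responses, ind, np.ones((60, 2)), ModelSpec(2, K=5), cfg)

    def test_sigma_draws_positive_definite(self, small_cohort):
        data, ind = small_cohort
        cfg = MCMCConfig(n_chains=2, n_adapt=40, n_burnin=40, n_posterior_total=200, seed=2)
        draws = run_mcmc(data.responses, ind, None, ModelSpec(1, K=5), cfg)
        for sig in draws.sigma_draws():
            assert np.linalg.eigvalsh(sig).min() > 0

    def test_covariate_model_stores_coefficients(self, small_cohort):
        data, ind = small_cohort
        design = design_matrix(data.covariates, 2).to_numpy()
        cfg = MCMCConfig(n_chains=2, n_adapt=30, n_burnin=30, n_posterior_total=60, seed=4)
        draws = run_mcmc(data.responses, ind, design, ModelSpec(2, K=5), cfg)
        assert "beta_ability" in draws.params and "beta_completion" in draws.params

    def test_draws_round_trip_to_disk(self, small_cohort, tmp_path):
        data, ind = small_cohort
        cfg = MCMCConfig(n_chains=2, n_adapt=10, n_burnin=10, n_posterior_total=20, seed=4)
        draws = run_mcmc(data.responses, ind, None, ModelSpec(1, K=5), cfg)
        paths = draws.save(tmp_path)
        assert all(p.exists() for p in paths)
        import pandas as pd
        frame = pd.read_csv(paths[0])
        assert set(frame.columns) == {"chain", "iteration", "parameter", "value"}


class TestConjugateUpdates:
    def test_sigma_gibbs_matches_closed_form(self):
        # with traits observed directly, the update is exact normal-inverse-Wishart:
        # Sigma | R ~ IW(I + R'R, df + N), whose mean is (I + R'R)/(df + N - 3)
        rng = np.random.default_rng(0)
        truth = np.array([[1.0, 0.5], [0.5, 2.0]])
        resid = rng.multivariate_normal([0, 0], truth, size=3000)
        prior = PriorConfig()
        post_scale = np.eye(2) + resid.T @ resid
        expected = post_scale / (prior.wishart_df + 3000 - 3)
        draws = np.mean(
            [sample_latent_covariance(resid, prior, rng)[0] for _ in range(4000)], axis=0)
        np.testing.assert_allclose(draws, expected, rtol=0.05)

    def test_prior_only_tau1_moments(self, small_cohort):
        # with a single item, tau1 drops out of the likelihood entirely,
        # so its draws must reproduce the N(0, 10) prior
        data, ind = small_cohort
        resp1 = type(data.responses)(data.responses.values[:, :1])
        ind1 = code_missingness(resp1)
        cfg = MCMCConfig(n_chains=2, n_adapt=400, n_burnin=400, n_posterior_total=8000, seed=5)
        draws = run_mcmc(resp1, ind1, None, ModelSpec(1, K=1), cfg)
        t1 = draws.get("tau1").ravel()
        assert abs(t1.mean()) < 0.4
        assert t1.var() == pytest.approx(10.0, rel=0.25)

    def test_prior_only_coefficients_with_null_design(self, small_cohort):
        # an all-zero design column makes the coefficient conditional equal its prior
        data, ind = small_cohort
        design = np.zeros((60, 1))
        cfg = MCMCConfig(n_chains=2, n_adapt=100, n_burnin=100, n_posterior_total=6000, seed=6)
        draws = run_mcmc(data.responses, ind, design, ModelSpec(2, K=5), cfg)
        for name in ("beta_ability", "beta_completion"):
            c = draws.get(name).ravel()
            assert abs(c.mean()) < 0.35
            assert c.var() == pytest.approx(10.0, rel=0.2)


class TestFitModel:
    def test_requires_covariates_for_model2(self, small_cohort):
        data, ind = small_cohort
        cfg = MCMCConfig(n_chains=2, n_adapt=5, n_burnin=5, n_posterior_total=4, seed=1)
        with pytest.raises(ValueError, match="covariate"):
            fit_model(data.responses, ind, None, 2, cfg)

    def test_tiny_sample_flags_not_converged(self, small_cohort, fast_cfg):
        # far too few draws to pass the ESS rule: exercises the failure path
        data, ind = small_cohort
        report = fit_model(data.responses, ind, data.covariates, 4, fast_cfg)
        assert report.verdict == "NOT_CONVERGED"
        assert report.failures

    def test_escalation_happens_once_then_flagged(self, small_cohort, fast_cfg):
        data, ind = small_cohort
        report = fit_model(data.responses, ind, data.covariates, 1, fast_cfg)
        assert report.verdict == "NOT_CONVERGED"
        assert report.metadata.get("escalated_burnin") is True
        assert report.config["n_burnin"] == fast_cfg.escalated_burnin

    def test_relaxed_rules_can_converge(self, small_cohort):
        data, ind = small_cohort
        cfg = MCMCConfig(n_chains=2, n_adapt=300, n_burnin=300, n_posterior_total=1000, seed=3)
        rules = ConvergenceRules(rhat_max=1.2, mcse_max=np.inf, ess_min=0.0)
        report = fit_model(data.responses, ind, None, 1, cfg, rules=rules, escalate=False)
        assert report.verdict == "CONVERGED"
        assert {"mean", "sd", "hpdi_low", "hpdi_high", "rhat", "ess", "mcse"} <= set(
            report.table.columns)

    def test_report_serializes(self, small_cohort, fast_cfg, tmp_path):
        data, ind = small_cohort
        report = fit_model(data.responses, ind, None, 1, fast_cfg, escalate=False)
        paths = report.write(tmp_path)
        assert all(p.exists() for p in paths)
        import json
        payload = json.loads(paths[0].read_text())
        assert payload["verdict"] in {"CONVERGED", "NOT_CONVERGED"}
        assert payload["config"]["seed"] == fast_cfg.seed
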