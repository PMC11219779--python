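"""Likelihood, HMC sampler, constraint filtering and chain diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from boedpd import (Measurement, PriorEntry, PriorSpec,
                    effective_sample_size, filter_chain_by_constraints,
                    infer_posterior, log_likelihood, log_posterior, run_mcmc)
from boedpd.inference import (HMCSettings, log_likelihood_and_grad,
                              most_sensitive_parameter)
from boedpd.model_core import final_concentration

from conftest import as_chain


def _measurement(model, theta, design="Casp_act", u=1.0, offset_sd=0.0):
    y_hat = final_concentration(model, theta, u, design)
    return Measurement(design=design, u=u,
                       y_obs=y_hat * (1.0 + 0.1 * offset_sd),
                       noise_sd=0.1 * y_hat), y_hat


class TestLikelihood:

    def test_mode_value(self, model, feasible_theta):
        """At y_obs = y_hat the density is the Gaussian normalisation."""
        meas, y_hat = _measurement(model, feasible_theta)
        ll = log_likelihood(feasible_theta, meas, model)
        assert ll == pytest.approx(-np.log(np.sqrt(2 * np.pi) * 0.1 * y_hat),
                                   rel=1e-9)

    def test_one_sigma_displacement_costs_half(self, model, feasible_theta):
        meas0, _ = _measurement(model, feasible_theta)
        meas1, _ = _measurement(model, feasible_theta, offset_sd=1.0)
        assert log_likelihood(feasible_theta, meas1, model) == pytest.approx(
            log_likelihood(feasible_theta, meas0, model) - 0.5, abs=1e-9)

    def test_gradient_matches_central_differences(self, model,
                                                  feasible_theta):
        """Forward-sensitivity gradient vs a finite-difference oracle.

        Integrator tolerances are tightened for the check so that solver
        noise does not swamp the O(h^2) truncation error.
        """
        meas, _ = _measurement(model, feasible_theta, offset_sd=0.7)
        backend = model.backend
        old = backend.rtol, backend.atol
        backend.rtol, backend.atol = 1e-11, 1e-13
        try:
            _, grad = log_likelihood_and_grad(feasible_theta, meas, model)
            for j, name in enumerate(model.uncertain_names):
                h = 1e-5 * feasible_theta[name]
                hi = dict(feasible_theta)
                hi[name] += h
                lo = dict(feasible_theta)
                lo[name] -= h
                fd = (log_likelihood(hi, meas, model)
                      - log_likelihood(lo, meas, model)) / (2 * h)
                assert grad[j] == pytest.approx(fd, rel=1e-4), name
        finally:
            backend.rtol, backend.atol = old

    def test_linear_model_gradient_closed_form(self, production_model):
        """dC/dt = k gives y_hat = k tau: the gradient is analytic."""
        m = production_model
        k, y_obs = 5.0, 5.3
        meas = Measurement(design="Casp", u=0.0, y_obs=y_obs, noise_sd=0.5)
        ll, grad = log_likelihood_and_grad({"k": k}, meas, m)
        r, y_hat = 0.1, k * m.tau
        expected_ll = (-0.5 * np.log(2 * np.pi) - np.log(r * y_hat)
                       - (y_obs - y_hat) ** 2 / (2 * (r * y_hat) ** 2))
        expected_grad = (-1.0 / y_hat
                         + (y_obs - y_hat) * y_obs / (r ** 2 * y_hat ** 3)
                         ) * m.tau
        assert ll == pytest.approx(expected_ll, rel=1e-8)
        assert grad[0] == pytest.approx(expected_grad, rel=1e-6)

    def test_prior_dominated_limit(self, model, priors, feasible_theta):
        """With enormous noise the posterior reduces to the prior, up to
        the theta-dependent Gaussian normalisation -ln y_hat(theta)."""
        meas, _ = _measurement(model, feasible_theta)
        other = dict(feasible_theta)
        other["k_rep"] *= 1.5
        other["k_act"] *= 0.7
        big = 1e8
        d_post = (log_posterior(feasible_theta, meas, model, priors,
                                rel_err=big)
                  - log_posterior(other, meas, model, priors, rel_err=big))
        names = priors.names
        d_prior = (priors.log_density([feasible_theta[k] for k in names])
                   - priors.log_density([other[k] for k in names]))
        d_norm = -(np.log(final_concentration(model, feasible_theta, meas.u,
                                              meas.design))
                   - np.log(final_concentration(model, other, meas.u,
                                                meas.design)))
        assert d_post - d_prior == pytest.approx(d_norm, abs=1e-6)

    def test_unintegrable_theta_scores_minus_inf(self, model, priors,
                                                 feasible_theta):
        theta = {k: 1e12 for k in feasible_theta}
        meas, _ = _measurement(model, feasible_theta)
        assert log_posterior(theta, meas, model, priors) == -np.inf


class TestSampler:

    def test_correlated_gaussian_moments(self):
        """2-D Gaussian target: means within 3 MCSE, covariance within 10%."""
        cov = np.array([[1.0, 0.7], [0.7, 1.5]])
        prec = np.linalg.inv(cov)

        def target(x):
            return -0.5 * x @ prec @ x, -prec @ x

        raw = run_mcmc(target, np.zeros(2), 10_000, seed=13)
        ess = effective_sample_size(raw.samples).to_numpy()
        mcse = np.sqrt(np.diag(cov) / ess)
        assert np.all(np.abs(raw.samples.mean(axis=0)) < 3 * mcse)
        est = np.cov(raw.samples, rowvar=False)
        assert np.allclose(est, cov, rtol=0.10)

    def test_marginals_pass_ks_against_truth(self):
        """Detailed-balance smoke test at alpha = 0.01 (thinned draws)."""
        cov = np.array([[1.0, 0.7], [0.7, 1.5]])
        prec = np.linalg.inv(cov)

        def target(x):
            return -0.5 * x @ prec @ x, -prec @ x

        raw = run_mcmc(target, np.zeros(2), 12_000, seed=29)
        thinned = raw.samples[::6]
        for j in range(2):
            p = stats.kstest(thinned[:, j],
                             stats.norm(0, np.sqrt(cov[j, j])).cdf).pvalue
            assert p > 0.01

    def test_conjugate_normal_normal_reduction(self):
        """1-D linear model with known sigma has a closed-form posterior."""
        m0, s0, y, s = 1.0, 2.0, 3.0, 0.5
        var_post = 1.0 / (1.0 / s0 ** 2 + 1.0 / s ** 2)
        mean_post = var_post * (m0 / s0 ** 2 + y / s ** 2)

        def target(x):
            dp = -(x[0] - m0) / s0 ** 2 - (x[0] - y) / s ** 2
            lp = (-0.5 * (x[0] - m0) ** 2 / s0 ** 2
                  - 0.5 * (x[0] - y) ** 2 / s ** 2)
            return lp, np.array([dp])

        raw = run_mcmc(target, np.array([0.0]), 8000, seed=17)
        ess = effective_sample_size(raw.samples).iloc[0]
        mcse = np.sqrt(var_post / ess)
        assert raw.samples.mean() == pytest.approx(mean_post, abs=3 * mcse)
        assert raw.samples.std(ddof=1) == pytest.approx(
            np.sqrt(var_post), rel=0.10)

    def test_prior_recovery_without_data(self):
        """No likelihood term: marginal quantiles match the prior's."""
        def target(x):
            return -0.5 * x @ x, -x

        raw = run_mcmc(target, np.zeros(5), 8000, seed=23)
        qs = np.array([0.1, 0.25, 0.5, 0.75, 0.9])
        expected = stats.norm.ppf(qs)
        for j in range(5):
            got = np.quantile(raw.samples[:, j], qs)
            assert np.allclose(got, expected, atol=0.12)

    def test_nonfinite_init_rejected(self):
        def target(x):
            return -np.inf, None
        with pytest.raises(ValueError, match="not finite"):
            run_mcmc(target, np.zeros(2), 100, seed=0)

    def test_same_seed_same_chain(self, model, priors, feasible_theta):
        meas, _ = _measurement(model, feasible_theta, offset_sd=0.5)
        a = infer_posterior(meas, model, priors, n_samples=60, seed=4)
        b = infer_posterior(meas, model, priors, n_samples=60, seed=4)
        assert a.samples.equals(b.samples)

    def test_prior_mismatch_rejected(self, model, feasible_theta):
        meas, _ = _measurement(model, feasible_theta)
        wrong = PriorSpec(entries=(PriorEntry("x", 0.0, 1.0),))
        with pytest.raises(ValueError, match="uncertain_names"):
            infer_posterior(meas, model, wrong, n_samples=50, seed=0)


class TestConstraintFiltering:

    def test_all_feasible_is_a_no_op(self, model, feasible_theta):
        rows = pd.DataFrame([feasible_theta] * 4)
        chain = as_chain(rows)
        out = filter_chain_by_constraints(chain, model)
        assert out.retained_fraction == 1.0
        assert out.samples.equals(chain.samples)

    def test_planted_feasible_fraction_is_exact(self, model, feasible_theta,
                                                infeasible_theta):
        rows = pd.DataFrame([feasible_theta] * 3 + [infeasible_theta] * 7)
        out = filter_chain_by_constraints(as_chain(rows), model)
        assert out.retained_fraction == 0.30
        assert len(out) == 3

    def test_filtering_is_idempotent(self, model, feasible_theta,
                                     infeasible_theta):
        rows = pd.DataFrame([feasible_theta] * 3 + [infeasible_theta] * 7)
        once = filter_chain_by_constraints(as_chain(rows), model)
        twice = filter_chain_by_constraints(once, model)
        assert twice.samples.equals(once.samples)
        assert twice.retained_fraction == once.retained_fraction

    def test_survivor_at_high_dose_is_removed(self, model, feasible_theta):
        """A parameter set that still kills at u=100 violates the
        live-at-impotent-dose constraint."""
        hot = dict(feasible_theta)
        hot["k_act"] *= 50.0     # caspase fires even with repair intact
        rows = pd.DataFrame([feasible_theta, hot])
        out = filter_chain_by_constraints(as_chain(rows), model)
        assert len(out) == 1
        assert out.samples.iloc[0]["k_act"] == feasible_theta["k_act"]

    def test_empty_result_is_a_signal_not_an_error(self, model,
                                                   infeasible_theta):
        rows = pd.DataFrame([infeasible_theta] * 3)
        out = filter_chain_by_constraints(as_chain(rows), model)
        assert out.is_empty
        assert out.retained_fraction == 0.0


class TestEffectiveSampleSize:

    def test_iid_samples_have_full_ess(self):
        x = np.random.default_rng(1).standard_normal(10_000)
        ess = effective_sample_size(x[:, None]).iloc[0]
        assert ess == pytest.approx(10_000, rel=0.10)

    def test_ar1_closed_form(self):
        """AR(1) with rho = 0.5: ESS = n (1-rho)/(1+rho) = n/3."""
        rng = np.random.default_rng(2)
        n, rho = 20_000, 0.5
        x = np.empty(n)
        x[0] = rng.standard_normal()
        innov = rng.standard_normal(n) * np.sqrt(1 - rho ** 2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + innov[i]
        ess = effective_sample_size(x[:, None]).iloc[0]
        assert ess == pytest.approx(n / 3, rel=0.10)

    def test_duplicated_chain_halves_ess(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(5000)
        dup = np.repeat(x, 2)
        ess = effective_sample_size(dup[:, None]).iloc[0]
        assert ess == pytest.approx(5000, rel=0.15)

    def test_agrees_with_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(4)
        n, rho = 20_000, 0.7
        x = np.empty(n)
        x[0] = rng.standard_normal()
        innov = rng.standard_normal(n) * np.sqrt(1 - rho ** 2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + innov[i]
        ours = effective_sample_size(x[:, None]).iloc[0]
        theirs = float(arviz.ess(x[None, :]))
        assert ours == pytest.approx(theirs, rel=0.15)

    def test_constant_column_is_undefined(self):
        x = np.column_stack([np.ones(100), np.arange(100.0)])
        with pytest.warns(UserWarning, match="constant"):
            ess = effective_sample_size(x)
        assert np.isnan(ess.iloc[0])

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            effective_sample_size(np.ones((5, 2)))


def test_most_sensitive_parameter_is_stable(model, priors):
    name = most_sensitive_parameter(model, priors, "Casp_act", u=1.0)
    assert name in priors.names
    assert name == most_sensitive_parameter(model, priors, "Casp_act", u=1.0)
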