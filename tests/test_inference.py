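"""Gamma-likelihood MLE, Hessian uncertainties, MCMC sampling."""

import numpy as np
import pytest
from scipy import optimize, stats

from beadcal.inference import (FitSpec, fit_mle, gamma_loglik_full, gamma_negloglik,
                               hessian_errors, mcmc_sample)
from beadcal.models import psd_closed_form
from beadcal.spectra import SpectrumEstimate, log_bin_psd, avar_overlapping
from beadcal.simulate import SimulationConfig, simulate_trajectory

from conftest import FS, GAMMA, KAPPA, KT, gamma_sampled_psd


class TestCost:
    def test_single_point_minimized_at_data(self):
        yhat, eta = np.array([2.7]), np.array([1.0])
        r = optimize.minimize_scalar(
            lambda y: gamma_negloglik(yhat, eta, np.array([y])), bounds=(0.1, 20),
            method="bounded", options={"xatol": 1e-12})
        assert r.x == pytest.approx(yhat[0], rel=1e-6)

    def test_cost_difference_is_log_likelihood_ratio(self, rng):
        """Cost drops only parameter-independent constants, so differences
        between parameter vectors equal Gamma log-likelihood ratios."""
        yhat = rng.gamma(shape=3.0, scale=1.0, size=50)
        eta = np.full(50, 3.0)
        y1, y2 = np.full(50, 0.9), np.full(50, 1.3)
        dcost = gamma_negloglik(yhat, eta, y2) - gamma_negloglik(yhat, eta, y1)
        dll = (np.sum(stats.gamma.logpdf(yhat, a=eta, scale=y1 / eta))
               - np.sum(stats.gamma.logpdf(yhat, a=eta, scale=y2 / eta)))
        assert dcost == pytest.approx(dll, rel=1e-10)

    def test_linear_in_shapes(self, rng):
        yhat = rng.gamma(shape=2.0, scale=1.0, size=20)
        eta = np.full(20, 2.0)
        y = np.full(20, 1.1)
        assert gamma_negloglik(yhat, 2 * eta, y) == pytest.approx(
            2 * gamma_negloglik(yhat, eta, y))

    def test_rejects_nonpositive_model(self):
        with pytest.raises(ValueError):
            gamma_negloglik(np.ones(3), np.ones(3), np.array([1.0, 0.0, 1.0]))


class TestFitMle:
    def test_noiseless_fixed_point(self):
        f = np.fft.rfftfreq(1024, 1 / FS)[1:]
        y = psd_closed_form(f, GAMMA, KAPPA, KT, f_s=FS)
        est = SpectrumEstimate(kind="psd", abscissa=f, values=y,
                               shape=np.full(f.size, 3.0), f_s=FS, n_points_used=2048)
        fit = fit_mle(est, FitSpec(model="psd:lansdorp", kT=KT))
        assert fit.params["gamma"] == pytest.approx(GAMMA, rel=1e-6)
        assert fit.params["kappa"] == pytest.approx(KAPPA, rel=1e-6)

    def test_gradient_vanishes_at_reported_mle(self, rng):
        est = gamma_sampled_psd(rng)
        fit = fit_mle(est, FitSpec(model="psd:lansdorp", kT=KT))
        z = np.log([fit.params["gamma"], fit.params["kappa"]])
        h = 1e-5
        for i in range(2):
            e = np.zeros(2); e[i] = h
            def cost(zz):
                g, k = np.exp(zz)
                y = psd_closed_form(est.abscissa, g, k, KT, f_s=FS)
                return gamma_negloglik(est.values, est.shape, y)
            grad = (cost(z + e) - cost(z - e)) / (2 * h)
            assert abs(grad) < 1e-2 * abs(cost(z))  # relative flatness
            assert abs(grad) / max(abs(cost(z)), 1) < 1e-4

    def test_cutoffs_equal_pretruncation(self, rng):
        est = gamma_sampled_psd(rng)
        spec = FitSpec(model="psd:lansdorp", kT=KT, cutoffs=(1.0, 30.0))
        fit_a = fit_mle(est, spec)
        fit_b = fit_mle(est.truncated(1.0, 30.0), FitSpec(model="psd:lansdorp", kT=KT))
        assert fit_a.params == fit_b.params
        assert fit_a.n_points == fit_b.n_points

    def test_fixed_parameter_reduces_K(self, rng):
        est = gamma_sampled_psd(rng)
        fit = fit_mle(est, FitSpec(model="psd:lansdorp", kT=KT,
                                   fixed={"gamma": GAMMA}))
        assert fit.K == 1 and fit.free_names == ("kappa",)
        assert fit.params["gamma"] == GAMMA
        assert fit.errors is not None and "gamma" not in fit.errors

    def test_kind_mismatch_and_logbinned_rejected(self, rng):
        est = gamma_sampled_psd(rng)
        with pytest.raises(ValueError, match="av model"):
            fit_mle(est, FitSpec(model="av:lansdorp", kT=KT))
        with pytest.raises(ValueError, match="visualization-only"):
            fit_mle(log_bin_psd(est, 5), FitSpec(model="psd:lansdorp", kT=KT))

    def test_degenerate_spectrum_rejected(self):
        est = SpectrumEstimate(kind="psd", abscissa=np.arange(1.0, 11.0),
                               values=np.zeros(10), shape=np.ones(10), f_s=20.0,
                               n_points_used=100)
        with pytest.raises(ValueError, match="degenerate"):
            fit_mle(est, FitSpec(model="psd:lansdorp", kT=KT))

    def test_no_free_parameters_rejected(self):
        with pytest.raises(ValueError, match="free"):
            FitSpec(model="psd:lansdorp", fixed={"gamma": 1., "kappa": 1.}).free_names()

    def test_aic_identity(self, rng):
        est = gamma_sampled_psd(rng)
        fit = fit_mle(est, FitSpec(model="psd:lansdorp", kT=KT))
        assert fit.diagnostics.aic == 2 * fit.K - 2 * fit.loglik
        assert fit.loglik == pytest.approx(
            gamma_loglik_full(fit.values, fit.shape, fit.model_values))

    def test_mle_less_biased_than_unweighted_lsq(self):
        """At eta = 3 the Gamma skew biases unweighted least squares
        (measurably in gamma); the Gamma MLE median bias is smaller."""
        rng = np.random.default_rng(31)
        mle, lsq = [], []
        f = np.fft.rfftfreq(512, 1 / FS)[1:]
        y_true = psd_closed_form(f, GAMMA, KAPPA, KT, f_s=FS)
        for _ in range(400):
            yhat = rng.gamma(shape=3.0, scale=y_true / 3.0)
            est = SpectrumEstimate(kind="psd", abscissa=f, values=yhat,
                                   shape=np.full(f.size, 3.0), f_s=FS,
                                   n_points_used=1024)
            mle.append(fit_mle(est, FitSpec(model="psd:lansdorp", kT=KT)).params["gamma"])
            r = optimize.least_squares(
                lambda z: psd_closed_form(f, np.exp(z[0]), np.exp(z[1]), KT, f_s=FS) - yhat,
                np.log([GAMMA, KAPPA]))
            lsq.append(np.exp(r.x[0]))
        bias_mle = abs(np.median(mle) / GAMMA - 1)
        bias_lsq = abs(np.median(lsq) / GAMMA - 1)
        assert bias_mle < bias_lsq


class TestHessianErrors:
    def test_gamma_scale_model_fisher_information(self, rng):
        """One-parameter scale model: Var(theta_hat) = theta^2 / sum(eta)."""
        eta = rng.uniform(2, 6, size=200)
        yhat = rng.gamma(shape=eta, scale=1.0 / eta)
        theta_hat = np.sum(eta * yhat) / np.sum(eta)

        def cost(z):
            return gamma_negloglik(yhat, eta, np.full(eta.size, np.exp(z[0])))

        cov, err = hessian_errors(cost, np.log([theta_hat]))
        assert err[0] == pytest.approx(theta_hat / np.sqrt(np.sum(eta)), rel=1e-4)

    def test_quadratic_cost_exact_sigma(self):
        s = 0.17
        p0 = np.log(2.0)

        def cost(z):
            return (z[0] - p0) ** 2 / (2 * s**2)

        cov, err = hessian_errors(cost, np.array([p0]))
        # log-space sigma is s; natural-parameter error is theta * s
        assert err[0] == pytest.approx(2.0 * s, rel=1e-6)

    def test_indefinite_hessian_raises(self):
        with pytest.raises(np.linalg.LinAlgError, match="not positive definite"):
            hessian_errors(lambda z: -np.sum(z**2), np.zeros(2))


class TestMcmc:
    def test_same_seed_identical_samples(self, rng):
        est = gamma_sampled_psd(rng, bin_length=128)
        spec = FitSpec(model="psd:lansdorp", kT=KT)
        fit = fit_mle(est, spec)
        a = mcmc_sample(est, spec, fit, walkers=8, steps=150, seed=5)
        b = mcmc_sample(est, spec, fit, walkers=8, steps=150, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_gaussian_toy_percentile_width(self):
        """Sampling a known Gaussian cost: percentile half-width = sigma."""
        import emcee
        sigma = 0.2
        mu = np.log(3.0)

        def log_prob(z):
            return -np.sum((z - mu) ** 2, axis=-1) / (2 * sigma**2)

        sampler = emcee.EnsembleSampler(16, 1, log_prob, vectorize=True)
        sampler.random_state = np.random.RandomState(1).get_state()
        p0 = mu + 1e-3 * np.random.default_rng(1).standard_normal((16, 1))
        sampler.run_mcmc(p0, 4000, progress=False)
        chain = sampler.get_chain(discard=1000, flat=True)[:, 0]
        lo, hi = np.percentile(chain, [15.8, 84.2])
        assert 0.5 * (hi - lo) == pytest.approx(sigma, rel=0.05)

    def test_intervals_match_hessian_on_synthetic_fit(self, rng):
        est = gamma_sampled_psd(rng, bin_length=256)
        spec = FitSpec(model="psd:lansdorp", kT=KT)
        fit = fit_mle(est, spec)
        post = mcmc_sample(est, spec, fit, walkers=32, steps=600, seed=9)
        for name in ("gamma", "kappa"):
            assert post.intervals[name] == pytest.approx(fit.errors[name], rel=0.2)
        assert 0.1 <= post.acceptance_fraction <= 0.9


class TestEndToEnd:
    def test_av_calibration_recovers_truth(self):
        """Trajectory-level AV fits recover gamma and kappa to within 10%
        (about three times the empirical per-fit scatter at these
        conditions; reported sigmas are slightly optimistic because
        overlapping AV points are cross-correlated)."""
        for seed in range(3):
            cfg = SimulationConfig(n_samples=16384, f_s=FS, gamma=GAMMA, kappa=KAPPA,
                                   oversample=200, seed=12345 + seed)
            est = avar_overlapping(simulate_trajectory(cfg))
            fit = fit_mle(est, FitSpec(model="av:lansdorp", kT=KT))
            assert fit.params["gamma"] == pytest.approx(GAMMA, rel=0.10)
            assert fit.params["kappa"] == pytest.approx(KAPPA, rel=0.10)
            assert fit.errors is not None and fit.cov.shape == (2, 2)
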