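"""Gamma-likelihood maximum-likelihood fitting of thermal-motion models.

Experimental PSD and AV points are Gamma-distributed around the theory curve
y_k(gamma, kappa, ...) with known shape eta_k (Welch bin count, or half the
Allan edf), so the negative log-likelihood, up to a parameter-independent
constant, is

    l(theta) = sum_k eta_k [ yhat_k / y_k(theta) + ln y_k(theta) ].

For moderate eta the Gamma distribution is visibly skewed and unweighted
least squares is biased; minimizing l instead gives consistent estimates.
Minimization runs in log-parameter space (positivity for free) with
Nelder-Mead; uncertainties come from the inverted Hessian of l at the
minimum (delta method back to natural parameters), optionally cross-checked
by affine-invariant ensemble MCMC sampling of exp(-l) with percentile
intervals (15.8/84.2, one Gaussian sigma).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .diagnostics import Diagnostics, compute_diagnostics
from .models import ModelSpec, get_model
from .simulate import KT_ROOM
from .spectra import SpectrumEstimate

__all__ = [
    "FitSpec",
    "FitResult",
    "PosteriorSamples",
    "FitError",
    "gamma_negloglik",
    "gamma_loglik_full",
    "fit_mle",
    "hessian_errors",
    "mcmc_sample",
]


class FitError(RuntimeError):
    """Raised when the optimizer fails; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class FitSpec:
    """What to fit: model key, fixed parameters, guesses, cutoffs.

    ``fixed`` maps parameter names ('gamma', 'kappa', 'epsilon') to values
    held constant; remaining model parameters are free.  ``cutoffs`` is an
    inclusive (lo, hi) window on the abscissa (frequency in Hz or observation
    time in s); None leaves that side open.
    """

    model: str = "psd:lansdorp"
    kT: float = KT_ROOM
    fixed: dict = field(default_factory=dict)
    guesses: dict = field(default_factory=dict)
    cutoffs: tuple | None = None

    def free_names(self) -> tuple[str, ...]:
        spec = get_model(self.model)
        unknown = set(self.fixed) - set(spec.param_names)
        if unknown:
            raise ValueError(f"fixed parameters {sorted(unknown)} not in model {self.model!r}")
        free = tuple(p for p in spec.param_names if p not in self.fixed)
        if not free:
            raise ValueError("at least one parameter must remain free")
        return free


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of a thermal-motion model to a spectrum."""

    model_key: str
    params: dict                 # all model parameters, fitted and fixed
    free_names: tuple
    errors: dict | None          # 1-sigma standard errors of free params (None if Hessian bad)
    cov: np.ndarray | None       # covariance of free params, natural units
    cost: float                  # minimized l
    loglik: float                # full ln Lhat (constants included), for AIC
    n_points: int                # N_y used
    K: int                       # number of free parameters
    diagnostics: Diagnostics
    residuals: np.ndarray
    abscissa: np.ndarray
    values: np.ndarray
    shape: np.ndarray
    model_values: np.ndarray
    kT: float
    f_s: float
    warnings: tuple = ()

    def summary(self) -> str:
        lines = [f"model {self.model_key}: N_y={self.n_points}, K={self.K}"]
        for name in self.free_names:
            err = self.errors.get(name) if self.errors else None
            err_s = f" +/- {err:.3g}" if err is not None else " (no error: Hessian not PD)"
            lines.append(f"  {name} = {self.params[name]:.6g}{err_s}")
        for name, val in self.params.items():
            if name not in self.free_names:
                lines.append(f"  {name} = {val:.6g} (fixed)")
        d = self.diagnostics
        lines.append(f"  chi2_nu = {d.chi2_reduced:.3f} (nu={d.nu_y}), "
                     f"support F = {d.support:.3f}, p = {d.p_value:.3f}, AIC = {d.aic:.1f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class PosteriorSamples:
    """MCMC draws of the free parameters (natural units, post burn-in)."""

    names: tuple
    samples: np.ndarray          # (n_draws, K)
    percentiles: dict            # name -> (p15.8, p84.2)
    intervals: dict              # name -> half width (p84.2 - p15.8)/2
    acceptance_fraction: float
    seed: int
    warnings: tuple = ()


def gamma_negloglik(values, shapes, model_values) -> float:
    """Cost l = sum eta_k [yhat_k/y_k + ln y_k], constants dropped."""
    yhat = np.asarray(values, dtype=float)
    eta = np.asarray(shapes, dtype=float)
    y = np.asarray(model_values, dtype=float)
    if yhat.shape != eta.shape or eta.shape != y.shape[-yhat.ndim:]:
        raise ValueError("values, shapes and model_values must have matching lengths")
    if np.any(eta <= 0):
        raise ValueError("shape parameters must be positive")
    if np.any(y <= 0):
        raise ValueError("model evaluated non-positive; parameters outside the valid domain")
    out = np.sum(eta * (yhat / y + np.log(y)), axis=-1)
    return float(out) if out.ndim == 0 else out


def gamma_loglik_full(values, shapes, model_values) -> float:
    """Exact ln L = sum ln Gamma(yhat; shape eta_k, scale y_k/eta_k).

    Includes the Gamma-function and scale constants so that AIC values are
    comparable across models with different parameter counts.
    """
    yhat = np.asarray(values, dtype=float)
    eta = np.asarray(shapes, dtype=float)
    y = np.asarray(model_values, dtype=float)
    return float(np.sum(stats.gamma.logpdf(yhat, a=eta, scale=y / eta)))


# ---------------------------------------------------------------------------
# initial guesses
# ---------------------------------------------------------------------------

def _initial_guess(est: SpectrumEstimate, model: ModelSpec, kT: float) -> dict:
    """Closed-form starting point from the spectrum's gross features.

    PSD: kappa from equipartition on the band power, gamma from the
    half-plateau (corner) frequency.  AV: if the curve has an interior
    maximum, kappa from the peak height (AV_max = 0.3811 kT/kappa) and gamma
    from its location (tau_max = 1.89 gamma/kappa); otherwise gamma from the
    short-time diffusive rise 2 kT tau/(3 gamma) and kappa from the
    long-time tail 2 kT gamma/(kappa^2 tau).
    """
    x, v = est.abscissa, est.values
    if est.kind == "psd":
        df = np.median(np.diff(x))
        var = max(2.0 * float(np.sum(v)) * df, 1e-12)
        kappa0 = kT / var
        plateau = float(np.mean(v[: max(3, v.size // 50)]))
        below = np.nonzero(v < 0.5 * plateau)[0]
        f_c0 = x[below[0]] if below.size else x[v.size // 2]
        gamma0 = kappa0 / (2.0 * math.pi * max(f_c0, x[0]))
        eps0 = math.sqrt(max(float(np.min(v)) * est.f_s * 0.5, 1e-12))
    else:
        k_peak = int(np.argmax(v))
        if 0 < k_peak < v.size - 1:
            kappa0 = 0.3811 * kT / v[k_peak]
            gamma0 = kappa0 * x[k_peak] / 1.89
        else:
            gamma0 = 2.0 * kT * x[0] / (3.0 * v[0])
            kappa0 = math.sqrt(2.0 * kT * gamma0 / (v[-1] * x[-1]))
        eps0 = math.sqrt(max(0.5 * v[0] * x[0] * est.f_s, 1e-12))
    guess = {"gamma": abs(gamma0), "kappa": abs(kappa0), "epsilon": eps0}
    return {k: guess[k] for k in model.param_names}


# ---------------------------------------------------------------------------
# MLE
# ---------------------------------------------------------------------------

def _make_cost(est: SpectrumEstimate, model: ModelSpec, spec: FitSpec):
    """Cost over log free parameters; +inf outside the valid domain.

    The returned callable accepts a 1-D point or a 2-D (n, K) batch (used by
    the vectorized MCMC log-probability).
    """
    free = spec.free_names()
    x, yhat, eta = est.abscissa, est.values, est.shape

    def cost(z):
        z = np.asarray(z, dtype=float)
        batch = z.ndim == 2
        p = dict(spec.fixed)
        theta = np.exp(z)
        for i, name in enumerate(free):
            p[name] = theta[..., i, None] if batch else float(theta[i])
        with np.errstate(over="ignore", invalid="ignore"):
            y = model(x, p, spec.kT, est.f_s)
            y = np.broadcast_to(y, (z.shape[0], x.size)) if batch else np.asarray(y)
            bad = ~np.all(np.isfinite(y) & (y > 0), axis=-1)
            y = np.where((y > 0) & np.isfinite(y), y, 1.0)
            ll = np.sum(eta * (yhat / y + np.log(y)), axis=-1)
        if batch:
            ll = np.where(bad, np.inf, ll)
            return ll
        return math.inf if bad else float(ll)

    return cost, free


def fit_mle(estimate: SpectrumEstimate, spec: FitSpec) -> FitResult:
    """Maximum-likelihood fit of a registered model to a spectrum.

    Applies the abscissa cutoffs, minimizes the Gamma cost over the free
    parameters in log space with Nelder-Mead (one restart from a perturbed
    point on flat convergence), and returns estimates, Hessian-based
    standard errors and the full diagnostics bundle.  Deterministic given
    its inputs.
    """
    model = get_model(spec.model)
    if model.kind != estimate.kind:
        raise ValueError(f"model {spec.model!r} is a {model.kind} model but the "
                         f"estimate is a {estimate.kind}")
    if not estimate.fit_ok:
        raise ValueError("estimate is flagged visualization-only (e.g. log-binned); "
                         "fit the unbinned spectrum")
    est = estimate
    if spec.cutoffs is not None:
        est = est.truncated(*spec.cutoffs)
    free = spec.free_names()
    if est.n_values < len(free) + 1:
        raise ValueError(f"cutoffs retain {est.n_values} points; need at least {len(free) + 1}")
    if np.all(est.values == 0):
        raise ValueError("degenerate spectrum: all values are zero")

    cost, free = _make_cost(est, model, spec)
    guess = dict(_initial_guess(est, model, spec.kT), **spec.guesses)
    z0 = np.log([guess[name] for name in free])
    opt = optimize.minimize(cost, z0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxfev": 10_000})
    if not opt.success or not np.isfinite(opt.fun):
        opt2 = optimize.minimize(cost, z0 + 0.3, method="Nelder-Mead",
                                 options={"xatol": 1e-8, "fatol": 1e-10, "maxfev": 10_000})
        if opt2.success and np.isfinite(opt2.fun) and opt2.fun <= opt.fun:
            opt = opt2
        elif not np.isfinite(opt.fun):
            raise FitError(f"optimizer failed: {opt.message}", trace=opt)
    z_hat = opt.x

    fit_warnings: list[str] = []
    errors: dict | None = None
    cov = None
    try:
        cov, errs = hessian_errors(cost, z_hat)
        errors = dict(zip(free, errs))
    except np.linalg.LinAlgError as exc:
        fit_warnings.append(f"Hessian not positive definite ({exc}); standard errors "
                            "unavailable — consider MCMC sampling")
        warnings.warn(fit_warnings[-1])

    params = dict(spec.fixed)
    for name, z in zip(free, z_hat):
        params[name] = float(math.exp(z))
    p_eval = dict(params)
    y_fit = np.asarray(model(est.abscissa, p_eval, spec.kT, est.f_s), dtype=float)
    loglik = gamma_loglik_full(est.values, est.shape, y_fit)
    diag = compute_diagnostics(est.values, est.shape, y_fit, K=len(free), logL_hat=loglik)
    from .diagnostics import normalized_residuals
    res = normalized_residuals(est.values, est.shape, y_fit)
    return FitResult(
        model_key=spec.model, params=params, free_names=free, errors=errors, cov=cov,
        cost=float(opt.fun), loglik=loglik, n_points=est.n_values, K=len(free),
        diagnostics=diag, residuals=res, abscissa=est.abscissa, values=est.values,
        shape=est.shape, model_values=y_fit, kT=spec.kT, f_s=est.f_s,
        warnings=tuple(fit_warnings))


# ---------------------------------------------------------------------------
# uncertainties
# ---------------------------------------------------------------------------

_HESS_STEP = 1e-3  # log-space central-difference step


def hessian_errors(cost, z_hat, step: float = _HESS_STEP):
    """Covariance and standard errors from the inverted Hessian at the MLE.

    The Hessian of the cost is built by central differences in log-parameter
    space (step ``step``, i.e. ~0.1% relative in natural units) and inverted;
    the delta method (d theta / d ln theta = theta) maps the covariance to
    natural units.  Raises ``numpy.linalg.LinAlgError`` when the Hessian is
    not positive definite rather than silently pseudo-inverting.
    """
    z_hat = np.asarray(z_hat, dtype=float)
    k = z_hat.size
    H = np.empty((k, k))
    f0 = cost(z_hat)
    for i in range(k):
        ei = np.zeros(k); ei[i] = step
        H[i, i] = (cost(z_hat + ei) - 2.0 * f0 + cost(z_hat - ei)) / step**2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = step
            H[i, j] = H[j, i] = (
                cost(z_hat + ei + ej) - cost(z_hat + ei - ej)
                - cost(z_hat - ei + ej) + cost(z_hat - ei - ej)) / (4.0 * step**2)
    eigvals = np.linalg.eigvalsh(H)
    if np.any(eigvals <= 0) or not np.all(np.isfinite(H)):
        raise np.linalg.LinAlgError(
            f"Hessian of the cost is not positive definite (eigenvalues {eigvals})")
    cov_log = np.linalg.inv(H)
    theta = np.exp(z_hat)
    cov_nat = cov_log * np.outer(theta, theta)
    return cov_nat, np.sqrt(np.diag(cov_nat))


def mcmc_sample(estimate: SpectrumEstimate, spec: FitSpec, fit: FitResult,
                walkers: int = 32, steps: int = 2500, seed: int = 0,
                burn_fraction: float = 0.25) -> PosteriorSamples:
    """Ensemble-MCMC sampling of exp(-l) around the MLE.

    Walkers start in a small Gaussian ball around the best-fit point in log
    space; the first ``burn_fraction`` of steps is discarded.  Standard
    errors are reported as half the spread between the 15.8th and 84.2nd
    percentiles (one sigma for a Gaussian posterior).  Seed-reproducible.
    """
    import emcee

    model = get_model(spec.model)
    est = estimate if spec.cutoffs is None else estimate.truncated(*spec.cutoffs)
    cost, free = _make_cost(est, model, spec)
    ndim = len(free)
    if walkers < 2 * ndim:
        raise ValueError("need at least 2 walkers per free parameter")
    z_hat = np.log([fit.params[name] for name in free])
    rng = np.random.default_rng(seed)
    p0 = z_hat + 1e-4 * rng.standard_normal((walkers, ndim))

    def log_prob(z):
        return -cost(np.atleast_2d(z))

    sampler = emcee.EnsembleSampler(walkers, ndim, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, steps, progress=False)
    burn = int(burn_fraction * steps)
    chain = sampler.get_chain(discard=burn, flat=True)
    samples = np.exp(chain)
    acc = float(np.mean(sampler.acceptance_fraction))
    warns: list[str] = []
    if not 0.1 <= acc <= 0.9:
        warns.append(f"MCMC acceptance fraction {acc:.2f} outside [0.1, 0.9]; "
                     "treat the intervals with caution")
        warnings.warn(warns[-1])
    percentiles, intervals = {}, {}
    for i, name in enumerate(free):
        lo, hi = np.percentile(samples[:, i], [15.8, 84.2])
        percentiles[name] = (float(lo), float(hi))
        intervals[name] = float(0.5 * (hi - lo))
        if not lo <= fit.params[name] <= hi:
            warns.append(f"MLE for {name} lies outside the central posterior interval")
    return PosteriorSamples(names=tuple(free), samples=samples, percentiles=percentiles,
                            intervals=intervals, acceptance_fraction=acc, seed=seed,
                            warnings=tuple(warns))
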