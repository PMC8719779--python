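"""Closed-form PSD and Allan-variance models for a trapped, video-tracked bead.

The overdamped Langevin equation gives a Lorentzian position PSD

    P(f) = kT / (2 pi^2 gamma (f_c^2 + f^2)),      f_c = kappa/(2 pi gamma).

A video camera modifies what is actually measured in three ways, each with a
closed-form correction:

* exposure blur — averaging over the shutter time tau0 multiplies the PSD by
  I(f) = sinc^2(f tau0) = sin^2(pi f tau0)/(pi f tau0)^2;
* aliasing — sampling at f_s folds all frequencies f + n f_s onto the band
  0 < f < f_s/2, so the measured PSD is the lattice sum over n;
* tracking error — Gaussian localization noise of standard deviation epsilon
  adds a flat term epsilon^2/f_s.

For the zero-dead-time case tau0 = tau_s the blurred, aliased sum has an
exact closed form (``psd_closed_form``); with negligible exposure (I == 1)
the aliased Lorentzian also sums in closed form (``psd_aliased_lorentzian``).
The Allan variance of the same process has its own closed form
(``av_thermal``), which implicitly contains the zero-dead-time exposure blur;
tracking error adds epsilon^2 tau_s / tau.

All PSDs are two-sided spectral densities reported on positive frequencies
(integral of P over the whole frequency line = variance), so white noise of
variance epsilon^2 sampled at f_s sits at the level epsilon^2/f_s.  Units:
nm^2/Hz (PSD), nm^2 (AV), Hz, s, pN, pN nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .simulate import KT_ROOM

__all__ = [
    "ThermalParams",
    "psd_lorentzian",
    "exposure_filter",
    "psd_aliased_sum",
    "psd_aliased_lorentzian",
    "psd_closed_form",
    "psd_with_tracking",
    "av_thermal",
    "av_with_tracking",
    "ModelSpec",
    "MODELS",
    "get_model",
    "register_model",
]


@dataclass(frozen=True)
class ThermalParams:
    """Physical parameters of the trapped-bead model.

    gamma : drag coefficient, pN s/nm;  kappa : spring constant, pN/nm;
    epsilon : tracking error, nm;  kT : thermal energy, pN nm;
    f_s : sampling rate, Hz;  tau0 : exposure time, s (default 1/f_s,
    zero dead time).
    """

    gamma: float
    kappa: float
    f_s: float
    kT: float = KT_ROOM
    epsilon: float = 0.0
    tau0: float | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.f_s <= 0:
            raise ValueError("f_s must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.tau0 is not None and not (0.0 < self.tau0 <= 1.0 / self.f_s):
            raise ValueError("tau0 must satisfy 0 < tau0 <= 1/f_s")

    @property
    def corner_frequency(self) -> float:
        return self.kappa / (2.0 * math.pi * self.gamma)

    @property
    def relaxation_time(self) -> float:
        return self.gamma / self.kappa

    @property
    def exposure_time(self) -> float:
        return 1.0 / self.f_s if self.tau0 is None else self.tau0


def psd_lorentzian(f, gamma, kappa, kT=KT_ROOM):
    """Unaliased, unblurred Lorentzian PSD of the trapped bead, nm^2/Hz."""
    f = np.asarray(f, dtype=float)
    f_c = kappa / (2.0 * np.pi * gamma)
    return kT / (2.0 * np.pi**2 * gamma * (f_c**2 + f**2))


def exposure_filter(f, tau0):
    """Power attenuation sin^2(pi f tau0)/(pi f tau0)^2 of a boxcar exposure.

    Dimensionless, in (0, 1]; the f -> 0 limit is exactly 1.
    """
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    x = np.pi * np.asarray(f, dtype=float) * tau0
    return np.sinc(x / np.pi) ** 2  # np.sinc(u) = sin(pi u)/(pi u)


def psd_aliased_sum(f, gamma, kappa, kT=KT_ROOM, f_s=None, tau0=None, tol=1e-8,
                    max_terms=10_000_000):
    """Aliased, exposure-filtered PSD by direct lattice summation.

    Evaluates sum_n P(|f + n f_s|) I(|f + n f_s|) for scalar or vector f in
    the open Nyquist band, truncating adaptively once an analytic bound on
    the remaining 1/f^2 (Lorentzian) tail falls below ``tol`` of the partial
    sum.  ``tau0=None`` means tau0 = tau_s (full-frame exposure); ``tau0=0``
    disables the blur (dead-time limit), in which case prefer the exact
    ``psd_aliased_lorentzian``.  This routine is the slow oracle for the
    closed forms and the general tau0 < tau_s case.
    """
    if f_s is None:
        raise ValueError("f_s is required")
    f = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any((f <= 0) | (f >= f_s / 2)):
        raise ValueError("frequencies must lie strictly inside (0, f_s/2)")
    if tau0 is None:
        tau0 = 1.0 / f_s

    def term(g):
        p = psd_lorentzian(g, gamma, kappa, kT)
        if tau0 > 0:
            p = p * exposure_filter(g, tau0)
        return p

    total = term(f).astype(float)
    n = 1
    block = 64
    c_tail = kT / (2.0 * np.pi**2 * gamma)  # P(f) <= c_tail / f^2
    while n <= max_terms:
        hi = min(n + block - 1, max_terms)
        ns = np.arange(n, hi + 1, dtype=float)
        g_plus = f[:, None] + ns[None, :] * f_s
        g_minus = np.abs(f[:, None] - ns[None, :] * f_s)
        total += term(g_plus).sum(axis=1) + term(g_minus).sum(axis=1)
        n = hi + 1
        # analytic bound on the omitted |n'| >= n terms; with blur the
        # integrand also carries I(f) <= 1/(pi f tau0)^2, so the tail decays
        # as f^-4 instead of the bare Lorentzian's f^-2
        if tau0 > 0:
            c4 = c_tail / (np.pi * tau0) ** 2
            tail = 2.0 * c4 / (3.0 * f_s**4 * max(n - 2, 1) ** 3)
        else:
            tail = 2.0 * c_tail / (f_s**2 * max(n - 2, 1))
        if np.all(tail <= tol * total):
            break
        block = min(block * 2, 100_000)
    else:
        raise RuntimeError("aliasing sum did not converge within max_terms")
    return total if total.size > 1 else float(total[0])


def psd_aliased_lorentzian(f, gamma, kappa, kT=KT_ROOM, f_s=None):
    """Aliased Lorentzian PSD with negligible exposure time (dead-time limit).

    The lattice sum of the Lorentzian alone is exactly

        P(f) = (kT / (2 pi gamma f_c f_s)) * sinh(a) / (cosh(a) - cos(2 pi f/f_s)),

    with a = 2 pi f_c/f_s, evaluated here in an overflow-free form.
    """
    if f_s is None:
        raise ValueError("f_s is required")
    f = np.asarray(f, dtype=float)
    f_c = kappa / (2.0 * np.pi * gamma)
    a = 2.0 * np.pi * f_c / f_s
    theta = 2.0 * np.pi * f / f_s
    # multiply num/denom by 2 exp(-a): stable for any a
    num = -np.expm1(-2.0 * a)
    den = np.expm1(-a) ** 2 + 4.0 * np.exp(-a) * np.sin(theta / 2.0) ** 2
    return kT / (2.0 * np.pi * gamma * f_c * f_s) * num / den


def psd_closed_form(f, gamma, kappa, kT=KT_ROOM, f_s=None):
    """Exact aliased + exposure-blurred PSD for zero dead time (tau0 = tau_s).

    Closed form of the full lattice sum:

        P(f) = (2 kT gamma / kappa^3) *
               (kappa + 2 gamma f_s sin^2(pi f/f_s) * sinh(x) / (cos(2 pi f/f_s) - cosh(x))),

    x = kappa/(gamma f_s).  The sinh/(cos - cosh) ratio is evaluated as
    expm1(-2x) / (expm1(-x)^2 + 4 e^-x sin^2(pi f/f_s)), which neither
    overflows for stiff traps (large x) nor cancels for soft ones.
    """
    if f_s is None:
        raise ValueError("f_s is required")
    f = np.asarray(f, dtype=float)
    x = kappa / (gamma * f_s)
    s2 = np.sin(np.pi * f / f_s) ** 2
    q = np.expm1(-2.0 * x) / (np.expm1(-x) ** 2 + 4.0 * np.exp(-x) * s2)
    return 2.0 * kT * gamma / kappa**3 * (kappa + 2.0 * gamma * f_s * s2 * q)


def psd_with_tracking(f, gamma, kappa, epsilon, kT=KT_ROOM, f_s=None):
    """Zero-dead-time PSD plus the flat tracking-error term epsilon^2/f_s."""
    return psd_closed_form(f, gamma, kappa, kT=kT, f_s=f_s) + epsilon**2 / f_s


# Series threshold for the AV bracket: below u = kappa tau / gamma ~ 3e-3 the
# direct expression loses precision to cancellation (bracket ~ u^2/3 out of
# O(1/u) terms, float error ~ u^-3 * eps), while the truncated series errs as
# ~u^3; u = 3e-3 balances both at ~2e-8 relative.
_AV_SERIES_U = 3e-3


def av_thermal(tau, gamma, kappa, kT=KT_ROOM):
    """Thermal-motion Allan variance of the trapped bead, nm^2.

    With u = tau/tau_c = kappa tau / gamma:

        AV(tau) = (2 kT gamma / (kappa^2 tau)) *
                  [1 + (2/u) e^-u - (1/(2u)) e^-2u - 3/(2u)].

    The printed source formula is typographically ambiguous about the 2's in
    the exponential prefactors; the coefficients used here are fixed uniquely
    by the requirements that AV -> 2 kT tau/(3 gamma) as tau -> 0 (series of
    the bracket: u^2/3 - u^3/4 + 7u^4/60 - ...), AV -> 2 kT gamma/(kappa^2 tau)
    as tau -> infinity, and that the maximum falls at tau ~= 1.89 tau_c.
    The bracket switches to its series for u < 1e-2 to avoid catastrophic
    cancellation.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    u = kappa * tau / np.asarray(gamma, dtype=float)
    u_safe = np.where(u < _AV_SERIES_U, 1.0, u)
    direct = (1.0 + (2.0 / u_safe) * np.exp(-u_safe)
              - np.exp(-2.0 * u_safe) / (2.0 * u_safe) - 1.5 / u_safe)
    series = u**2 / 3.0 - u**3 / 4.0 + 7.0 * u**4 / 60.0
    bracket = np.where(u < _AV_SERIES_U, series, direct)
    return 2.0 * kT * gamma / (kappa**2 * tau) * bracket


def av_with_tracking(tau, gamma, kappa, epsilon, kT=KT_ROOM, tau_s=None):
    """Thermal AV plus the tracking-error term epsilon^2 tau_s / tau."""
    if tau_s is None:
        raise ValueError("tau_s is required")
    tau = np.asarray(tau, dtype=float)
    return av_thermal(tau, gamma, kappa, kT=kT) + epsilon**2 * tau_s / tau


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A fittable theory curve: evaluates y(x) given named physical parameters.

    ``fn(x, params, kT, f_s)`` must broadcast over leading axes of the values
    in ``params`` (used by the vectorized MCMC log-probability).
    """

    key: str
    kind: str                      # 'psd' or 'av'
    param_names: tuple[str, ...]   # free-able physical parameters, in order
    fn: Callable[..., np.ndarray]

    def __call__(self, x, params: dict, kT: float, f_s: float):
        return self.fn(x, params, kT, f_s)


def _m_psd_aliased(x, p, kT, f_s):
    return psd_aliased_lorentzian(x, p["gamma"], p["kappa"], kT=kT, f_s=f_s)


def _m_psd_lansdorp(x, p, kT, f_s):
    return psd_closed_form(x, p["gamma"], p["kappa"], kT=kT, f_s=f_s)


def _m_psd_lansdorp_tracking(x, p, kT, f_s):
    return (psd_closed_form(x, p["gamma"], p["kappa"], kT=kT, f_s=f_s)
            + p["epsilon"] ** 2 / f_s)


def _m_av_lansdorp(x, p, kT, f_s):
    return av_thermal(x, p["gamma"], p["kappa"], kT=kT)


def _m_av_lansdorp_tracking(x, p, kT, f_s):
    return (av_thermal(x, p["gamma"], p["kappa"], kT=kT)
            + p["epsilon"] ** 2 / (f_s * x))


MODELS: dict[str, ModelSpec] = {}


def register_model(key: str, kind: str, param_names: Sequence[str],
                   fn: Callable[..., np.ndarray], overwrite: bool = False) -> ModelSpec:
    """Register a (possibly user-defined) model curve for fitting.

    ``fn(x, params, kT, f_s)`` receives the abscissa grid (frequencies in Hz
    for ``kind='psd'``, observation times in s for ``kind='av'``) and a dict
    of parameter values, and must return the model curve (> 0 everywhere).
    """
    if kind not in ("psd", "av"):
        raise ValueError("kind must be 'psd' or 'av'")
    if key in MODELS and not overwrite:
        raise ValueError(f"model key {key!r} already registered")
    spec = ModelSpec(key=key, kind=kind, param_names=tuple(param_names), fn=fn)
    MODELS[key] = spec
    return spec


def get_model(key: str) -> ModelSpec:
    try:
        return MODELS[key]
    except KeyError:
        raise KeyError(f"unknown model key {key!r}; registered: {sorted(MODELS)}") from None


register_model("psd:lorentzian-aliased", "psd", ("gamma", "kappa"), _m_psd_aliased)
register_model("psd:lansdorp", "psd", ("gamma", "kappa"), _m_psd_lansdorp)
register_model("psd:lansdorp+tracking", "psd", ("gamma", "kappa", "epsilon"),
               _m_psd_lansdorp_tracking)
register_model("av:lansdorp", "av", ("gamma", "kappa"), _m_av_lansdorp)
register_model("av:lansdorp+tracking", "av", ("gamma", "kappa", "epsilon"),
               _m_av_lansdorp_tracking)
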