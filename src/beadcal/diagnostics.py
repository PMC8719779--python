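"""Fit-quality metrics for Gamma-likelihood spectral fits.

Each experimental PSD/AV point is Gamma-distributed with shape eta_k and
mean y_k, hence standard deviation sigma_k = y_k / sqrt(eta_k).  The
normalized residuals Delta_k = (yhat_k - y_k)/sigma_k should then be
unit-variance and, for moderate eta, close to Gaussian, which justifies the
chi-squared machinery: reduced chi^2, the support F (chi-squared CDF at the
observed chi^2), and the complementary p-value 1 - F.  Model comparison uses
the Akaike information criterion, AIC = 2K - 2 ln(Lhat); a model is preferred
only when every rival trails by Delta_AIC >= 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "Diagnostics",
    "normalized_residuals",
    "reduced_chi2",
    "support",
    "aic",
    "compare_models",
]


@dataclass(frozen=True)
class Diagnostics:
    """Summary of fit quality for one spectral fit."""

    chi2: float
    nu_y: int
    chi2_reduced: float
    support: float      # F, the chi-squared CDF at chi2
    p_value: float      # 1 - F
    aic: float

    def as_dict(self) -> dict:
        return {"chi2": self.chi2, "nu_y": self.nu_y, "chi2_reduced": self.chi2_reduced,
                "support": self.support, "p_value": self.p_value, "aic": self.aic}


def normalized_residuals(values, shapes, model_values) -> np.ndarray:
    """Delta_k = (yhat_k - y_k) / (y_k / sqrt(eta_k)).

    The denominator is the Gamma-model standard deviation of the k-th
    experimental value, which makes the residuals unit-variance when the
    model is correct.
    """
    yhat = np.asarray(values, dtype=float)
    eta = np.asarray(shapes, dtype=float)
    y = np.asarray(model_values, dtype=float)
    if np.any(eta <= 0):
        raise ValueError("shape parameters must be positive")
    if np.any(y <= 0):
        raise ValueError("model values must be positive")
    return (yhat - y) * np.sqrt(eta) / y


def reduced_chi2(residuals, K: int) -> tuple[float, int]:
    """(chi^2_nu, nu_y) with nu_y = N_y - K free parameters removed."""
    r = np.asarray(residuals, dtype=float)
    nu = r.size - int(K)
    if nu <= 0:
        raise ValueError(f"need more points than free parameters (N_y={r.size}, K={K})")
    return float(np.sum(r * r) / nu), nu


def support(chi2: float, nu: float) -> float:
    """Chi-squared distribution function F at the observed chi^2.

    F = P(nu/2, chi2/2), the regularized lower incomplete gamma function;
    the p-value is 1 - F.  Values of F near 1 flag fits whose chi^2 is
    improbably large under the model.
    """
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if nu <= 0:
        raise ValueError("nu must be positive")
    return float(special.gammainc(nu / 2.0, chi2 / 2.0))


def aic(logL_hat: float, K: int) -> float:
    """Akaike information criterion 2K - 2 ln(Lhat)."""
    if K < 0:
        raise ValueError("K must be non-negative")
    return 2.0 * K - 2.0 * logL_hat


def compute_diagnostics(values, shapes, model_values, K: int, logL_hat: float) -> Diagnostics:
    """Full diagnostics bundle from data, model curve and fitted likelihood."""
    res = normalized_residuals(values, shapes, model_values)
    chi2_nu, nu = reduced_chi2(res, K)
    chi2 = chi2_nu * nu
    F = support(chi2, nu)
    return Diagnostics(chi2=chi2, nu_y=nu, chi2_reduced=chi2_nu, support=F,
                       p_value=1.0 - F, aic=aic(logL_hat, K))


def compare_models(fits) -> dict:
    """Rank fits of the *same* spectrum by AIC.

    Returns a dict with the AIC-sorted order, the Delta_AIC values, and the
    preferred fit — declared only when all rivals have Delta_AIC >= 4,
    otherwise ``preferred`` is None and the models are reported
    indistinguishable.  Raises if the fits were made on different data.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        if (f.abscissa.shape != ref.abscissa.shape
                or not np.allclose(f.abscissa, ref.abscissa)
                or not np.allclose(f.values, ref.values)):
            raise ValueError("fits were performed on different spectra; AIC not comparable")
    aics = np.array([f.diagnostics.aic for f in fits])
    order = np.argsort(aics, kind="stable")
    delta = aics - aics.min()
    runner_up = float(np.sort(delta)[1])
    preferred = fits[order[0]] if runner_up >= 4.0 else None
    return {
        "order": [fits[i].model_key for i in order],
        "aic": {f.model_key: float(a) for f, a in zip(fits, aics)},
        "delta_aic": {f.model_key: float(d) for f, d in zip(fits, delta)},
        "preferred": preferred.model_key if preferred is not None else None,
        "distinguishable": preferred is not None,
    }
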