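"""Experimental noise metrics of a bead trajectory: Welch PSD and overlapping AV.

Both metrics reduce an N_x-point trajectory to N_y values with known sampling
distributions — each point is Gamma-distributed around the theory curve with
a shape parameter eta that the Gamma-likelihood fit needs:

* PSD (Welch's method): the trajectory is split into M half-overlapping,
  Hann-windowed bins whose periodograms are averaged per frequency; eta = M
  for every point.  Values are two-sided spectral densities on the one-sided
  grid f_k = k f_s / L (DC dropped, Nyquist kept), so white noise of variance
  eps^2 sits at eps^2/f_s.

* Allan variance (octave-sampled, overlapping): one half the mean squared
  difference between averages of adjacent m-sample windows, stride one, for
  m = 2, 4, ..., 2^floor(log2(N_x/2)); eta_k = nu_k/2 where nu_k is the
  equivalent degrees of freedom.  nu_k is, by default, determined empirically:
  the dominant power-law noise at each observation time is identified by the
  lag-1 autocorrelation method and fed to the exact edf sum in
  :mod:`beadcal._edf`; the cruder approximation nu = N_x/m - 1 (non-
  overlapping bin count) is available with ``edf='approx'`` and is always an
  underestimate for thermal-motion-like noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._edf import ALPHA_CLASSES, edf_power_law
from .simulate import Trajectory

__all__ = [
    "SpectrumEstimate",
    "NoiseId",
    "psd_welch",
    "log_bin_psd",
    "avar_overlapping",
    "identify_noise_lag1",
    "edf_empirical",
    "edf_approximate",
    "LAG1_MIN_RATIO",
]

#: Minimum N_x / m for the lag-1 noise identifier to be considered reliable.
LAG1_MIN_RATIO = 32


@dataclass(frozen=True)
class NoiseId:
    """Dominant power-law noise at one AV observation time."""

    m: int                 # bin length (samples)
    alpha: int             # data-PSD exponent, clamped to [-2, 2] for edf use
    noise_class: str       # e.g. 'white', 'random-walk', 'drift'
    method: str            # 'lag1' or 'fallback'


@dataclass(frozen=True)
class SpectrumEstimate:
    """Experimental PSD or AV values with per-point Gamma shape parameters.

    abscissa: frequencies f_k (Hz, PSD) or observation times tau_k (s, AV),
    strictly increasing.  values: nm^2/Hz (PSD) or nm^2 (AV).  shape: Gamma
    shape eta_k > 0.  ``fit_ok`` is False for visualization-only estimates
    (e.g. log-binned PSDs).
    """

    kind: str
    abscissa: np.ndarray
    values: np.ndarray
    shape: np.ndarray
    f_s: float
    n_points_used: int
    meta: dict = field(default_factory=dict)
    fit_ok: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.abscissa, dtype=float)
        v = np.asarray(self.values, dtype=float)
        s = np.asarray(self.shape, dtype=float)
        if self.kind not in ("psd", "av"):
            raise ValueError("kind must be 'psd' or 'av'")
        if not (a.shape == v.shape == s.shape) or a.ndim != 1:
            raise ValueError("abscissa, values and shape must be 1-D arrays of equal length")
        if np.any(np.diff(a) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("values must be non-negative")
        if np.any(s <= 0):
            raise ValueError("shape parameters must be positive")
        object.__setattr__(self, "abscissa", a)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "shape", s)

    @property
    def n_values(self) -> int:
        return self.abscissa.size

    def truncated(self, lo: float | None = None, hi: float | None = None) -> "SpectrumEstimate":
        """Copy restricted to lo <= abscissa <= hi (inclusive cutoffs)."""
        mask = np.ones(self.n_values, dtype=bool)
        if lo is not None:
            mask &= self.abscissa >= lo
        if hi is not None:
            mask &= self.abscissa <= hi
        if not mask.any():
            raise ValueError("cutoffs remove every point")
        return replace(self, abscissa=self.abscissa[mask], values=self.values[mask],
                       shape=self.shape[mask])


# ---------------------------------------------------------------------------
# Welch PSD
# ---------------------------------------------------------------------------

def psd_welch(trajectory: Trajectory, n_half_overlapping_bins: int = 3,
              detrend: bool = True) -> SpectrumEstimate:
    """Welch power spectral density with Hann windowing, eta = M per point.

    The trajectory is split into M = ``n_half_overlapping_bins`` bins of
    length L = floor(2 N_x / (M+1)) overlapping by half (trailing samples
    discarded), each bin is mean-detrended (switchable), multiplied by the
    Hann window w_j = sqrt(8/3) sin^2(pi j / L) — the sqrt(8/3) amplitude
    factor implements the 8/3 power correction — and its periodogram
    |FFT|^2 / (f_s sum w^2) is averaged per frequency over bins.  The zero-
    frequency point is dropped.
    """
    M = int(n_half_overlapping_bins)
    if M < 1:
        raise ValueError("n_half_overlapping_bins must be >= 1")
    x = trajectory.positions
    n_x = x.size
    L = (2 * n_x) // (M + 1)
    if L < 8:
        raise ValueError(
            f"trajectory too short for {M} half-overlapping bins: bin length {L} < 8 "
            f"(need N_x >= {4 * (M + 1)})")
    hop = L // 2
    j = np.arange(L)
    w = math.sqrt(8.0 / 3.0) * np.sin(np.pi * j / L) ** 2
    w_norm = trajectory.f_s * np.sum(w**2)
    starts = hop * np.arange(M)
    segs = np.stack([x[s:s + L] for s in starts])
    if detrend:
        segs = segs - segs.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(segs * w, axis=1)) ** 2 / w_norm
    values = spec.mean(axis=0)[1:]          # drop DC, keep Nyquist
    freqs = np.fft.rfftfreq(L, d=trajectory.tau_s)[1:]
    shape = np.full(values.size, float(M))
    meta = {"M": M, "bin_length": L, "detrend": bool(detrend), "n_x": n_x}
    return SpectrumEstimate(kind="psd", abscissa=freqs, values=values, shape=shape,
                            f_s=trajectory.f_s, n_points_used=n_x, meta=meta)


def log_bin_psd(estimate: SpectrumEstimate, bins_per_decade: int = 10) -> SpectrumEstimate:
    """Logarithmically bin a PSD for visualizing power-law behavior.

    Values are arithmetically averaged and shapes summed within each log-
    frequency bin; empty bins are dropped.  The result is flagged unusable
    for fitting (binned points are no longer Gamma with the summed shape once
    the curve bends within a bin).
    """
    if estimate.kind != "psd":
        raise ValueError("log_bin_psd requires a PSD estimate")
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    f = estimate.abscissa
    lo = math.floor(math.log10(f[0]) * bins_per_decade)
    hi = math.ceil(math.log10(f[-1]) * bins_per_decade) + 1
    edges = 10.0 ** (np.arange(lo, hi + 1) / bins_per_decade)
    idx = np.digitize(f, edges)
    abscissa, values, shapes = [], [], []
    for b in np.unique(idx):
        mask = idx == b
        abscissa.append(np.exp(np.mean(np.log(f[mask]))))  # geometric bin center
        values.append(float(np.mean(estimate.values[mask])))
        shapes.append(float(np.sum(estimate.shape[mask])))
    meta = dict(estimate.meta, log_binned=True, bins_per_decade=bins_per_decade)
    return SpectrumEstimate(kind="psd", abscissa=np.array(abscissa), values=np.array(values),
                            shape=np.array(shapes), f_s=estimate.f_s,
                            n_points_used=estimate.n_points_used, meta=meta, fit_ok=False)


# ---------------------------------------------------------------------------
# Overlapping Allan variance
# ---------------------------------------------------------------------------

def _octave_bin_lengths(n_x: int) -> np.ndarray:
    k_max = int(math.floor(math.log2(n_x / 2)))
    return 2 ** np.arange(1, k_max + 1)

def _overlapping_avar_single(x: np.ndarray, m: int) -> float:
    """Overlapping AV at bin length m via cumulative sums (O(N) per tau)."""
    n = x.size
    c = np.concatenate(([0.0], np.cumsum(x)))
    means = (c[m:] - c[:-m]) / m            # window means, start indices 0..n-m
    d = means[m:] - means[:-m]              # pairs separated by m samples
    return float(np.sum(d * d) / (2.0 * d.size))


def avar_overlapping(trajectory: Trajectory, edf: str = "empirical") -> SpectrumEstimate:
    """Octave-sampled overlapping Allan variance with per-point Gamma shapes.

    For each bin length m_k = 2^k the AV is one half the mean squared
    difference between averages of adjacent m_k-sample windows whose start
    indices slide by one sample (M = N_x - 2 m_k + 1 window pairs separated
    by m_k samples); tau_k = m_k tau_s.  Shapes are eta_k = nu_k / 2 with
    nu_k the equivalent degrees of freedom (``edf='empirical'``, noise-
    identified; or ``edf='approx'``, nu = N_x/m - 1).
    """
    if edf not in ("empirical", "approx"):
        raise ValueError("edf must be 'empirical' or 'approx'")
    x = trajectory.positions
    n_x = x.size
    if n_x < 16:
        raise ValueError(f"need at least 16 samples for the Allan variance, got {n_x}")
    ms = _octave_bin_lengths(n_x)
    values = np.array([_overlapping_avar_single(x, int(m)) for m in ms])
    taus = ms * trajectory.tau_s
    noise_ids: list[NoiseId] = []
    if edf == "approx":
        nus = np.array([edf_approximate(int(m), n_x) for m in ms])
    else:
        noise_ids = _identify_noise_chain(x, ms)
        if noise_ids:
            nus = np.array([
                edf_empirical(nid, int(m), n_x) for nid, m in zip(noise_ids, ms)])
        else:
            warnings.warn("noise identification failed for every observation time; "
                          "falling back on approximate degrees of freedom")
            nus = np.array([edf_approximate(int(m), n_x) for m in ms])
            edf = "approx-fallback"
    meta = {"m_k": ms.tolist(), "edf_mode": edf, "n_x": n_x,
            "noise_id": [(nid.m, nid.alpha, nid.noise_class, nid.method)
                         for nid in noise_ids]}
    return SpectrumEstimate(kind="av", abscissa=taus, values=values,
                            shape=nus / 2.0, f_s=trajectory.f_s,
                            n_points_used=n_x, meta=meta)


def _identify_noise_chain(x: np.ndarray, ms: np.ndarray) -> list[NoiseId]:
    """Lag-1 noise id per octave, with the short-record fallback rule.

    Points with N_x/m < 32 inherit the class of the last reliable point; an
    empty list signals total failure (no reliable point at all).
    """
    n_x = x.size
    out: list[NoiseId] = []
    last_reliable: NoiseId | None = None
    for m in ms:
        m = int(m)
        if n_x / m >= LAG1_MIN_RATIO:
            nid = identify_noise_lag1(x, m)
            last_reliable = nid
            out.append(nid)
        elif last_reliable is not None:
            out.append(NoiseId(m=m, alpha=last_reliable.alpha,
                               noise_class=last_reliable.noise_class, method="fallback"))
        else:
            return []
    return out


def identify_noise_lag1(trajectory: Trajectory | np.ndarray, m: int,
                        max_diffs: int = 2) -> NoiseId:
    """Dominant power-law noise class of the m-averaged series (lag-1 method).

    The series is decimated into non-overlapping m-sample means z; the lag-1
    autocorrelation r1 gives delta = r1/(1+r1), and the data are first-
    differenced (up to ``max_diffs`` times) while delta > 1/4.  The exponent
    estimate is alpha = -round(2 delta) - 2 * (number of differences), which
    is exact in expectation for pure power-law noise.  Deterministic for a
    fixed series; refuses when N_x/m < 32, where the caller must apply the
    fallback rule (copy the last reliable class).
    """
    x = trajectory.positions if isinstance(trajectory, Trajectory) else np.asarray(trajectory, float)
    m = int(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    if x.size / m < LAG1_MIN_RATIO:
        raise ValueError(
            f"lag-1 noise identification unreliable for N_x/m = {x.size / m:.1f} < "
            f"{LAG1_MIN_RATIO}; use the fallback rule")
    n_bins = x.size // m
    z = x[: n_bins * m].reshape(n_bins, m).mean(axis=1)
    d = 0
    while True:
        zc = z - z.mean()
        denom = float(np.dot(zc, zc))
        if denom == 0.0:
            delta = 0.0
            break
        r1 = float(np.dot(zc[:-1], zc[1:])) / denom
        delta = r1 / (1.0 + r1) if r1 > -0.999 else -10.0
        if delta <= 0.25 or d >= max_diffs:
            break
        z = np.diff(z)
        d += 1
    alpha_raw = int(round(-2.0 * delta)) - 2 * d
    alpha = max(-2, min(2, alpha_raw))
    noise_class = "drift" if alpha_raw < -2 else ALPHA_CLASSES[alpha]
    return NoiseId(m=m, alpha=alpha, noise_class=noise_class, method="lag1")


def edf_empirical(noise: NoiseId | int, m: int, n_x: int) -> float:
    """Equivalent degrees of freedom of an overlapping AV point.

    ``noise`` is a :class:`NoiseId` (or a bare alpha exponent).  Uses the
    exact correlation-sum edf for the identified power-law class; for
    thermal-motion-like classes this always exceeds the non-overlapping
    approximation N_x/m - 1.
    """
    alpha = noise.alpha if isinstance(noise, NoiseId) else int(noise)
    return edf_power_law(alpha, m, n_x, overlapping=True)


def edf_approximate(m: int, n_x: int) -> float:
    """Approximate degrees of freedom nu = N_x/m - 1 (non-overlapping bins)."""
    if n_x <= m:
        raise ValueError(f"need n_x > m, got n_x={n_x}, m={m}")
    return n_x / m - 1.0
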