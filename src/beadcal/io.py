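"""Trajectory/spectrum file formats, calibration reports and the workflow driver.

File conventions (all plain text):

* trajectory CSV — header ``time_s,position_nm`` and two numeric columns, as
  written by the simulator; single-column files (one position per line, nm)
  are also accepted but then require the sampling rate explicitly.
* spectrum CSV — header ``abscissa,value,shape`` preceded by ``#``-prefixed
  JSON metadata lines.
* calibration report — a versioned JSON document containing everything
  needed to re-run the calibration (inputs, settings, seeds, estimates,
  uncertainties, diagnostics); floats round-trip exactly (repr serialization).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .diagnostics import compare_models
from .inference import FitResult, FitSpec, PosteriorSamples, fit_mle, mcmc_sample
from .simulate import KT_ROOM, Trajectory
from .spectra import SpectrumEstimate, avar_overlapping, psd_welch

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "write_spectrum",
    "read_spectrum",
    "CalibrationReport",
    "run_calibration",
]

REPORT_SCHEMA_VERSION = 1


def read_trajectory(path, f_s_override: float | None = None) -> Trajectory:
    """Read a one- or two-column numeric text file into a Trajectory.

    Two-column files are interpreted as (time_s, position_nm); the sampling
    rate is inferred from the time column, which must be uniform to 1e-6
    relative.  One-column files require ``f_s_override`` (Hz).  An optional
    single header line is skipped automatically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        try:
            data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric rows beyond a single header line ({exc})") from exc
    if data.shape[0] < 16:
        raise ValueError(f"{path}: need at least 16 samples, found {data.shape[0]}")
    if data.shape[1] == 1:
        if f_s_override is None:
            raise ValueError(f"{path}: single-column file requires an explicit sampling rate")
        return Trajectory(positions=data[:, 0], f_s=float(f_s_override))
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected 1 or 2 columns, found {data.shape[1]}")
    t, x = data[:, 0], data[:, 1]
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0 or np.any(np.abs(dt - dt_med) > 1e-6 * dt_med):
        raise ValueError(f"{path}: time column is not uniformly spaced (1e-6 relative)")
    f_s = 1.0 / dt_med
    if f_s_override is not None and abs(f_s_override - f_s) > 1e-6 * f_s:
        raise ValueError(f"{path}: --fs {f_s_override} conflicts with the time column ({f_s:.6g} Hz)")
    return Trajectory(positions=x, f_s=f_s)


def write_trajectory(path, trajectory: Trajectory) -> None:
    """Write ``time_s,position_nm`` CSV (time = index / f_s)."""
    out = np.column_stack([trajectory.times, trajectory.positions])
    np.savetxt(path, out, delimiter=",", header="time_s,position_nm", comments="")


def write_spectrum(path, est: SpectrumEstimate) -> None:
    """Write ``abscissa,value,shape`` CSV with a JSON metadata comment block."""
    meta = {"kind": est.kind, "f_s": est.f_s, "n_points_used": est.n_points_used,
            "fit_ok": est.fit_ok, **est.meta}
    header = "meta " + json.dumps(meta) + "\nabscissa,value,shape"
    out = np.column_stack([est.abscissa, est.values, est.shape])
    np.savetxt(path, out, delimiter=",", header=header)


def read_spectrum(path) -> SpectrumEstimate:
    path = Path(path)
    meta = {}
    with path.open() as fh:
        for line in fh:
            if line.startswith("# meta "):
                meta = json.loads(line[len("# meta "):])
                break
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    kind = meta.pop("kind", "psd")
    f_s = meta.pop("f_s")
    n_used = meta.pop("n_points_used", data.shape[0])
    fit_ok = meta.pop("fit_ok", True)
    return SpectrumEstimate(kind=kind, abscissa=data[:, 0], values=data[:, 1],
                            shape=data[:, 2], f_s=f_s, n_points_used=int(n_used),
                            meta=meta, fit_ok=fit_ok)


# ---------------------------------------------------------------------------
# calibration workflow
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationReport:
    """Self-describing record of one calibration run (JSON round-trippable)."""

    schema_version: int
    software_version: str
    input: dict          # file, n_x, f_s
    method: str          # 'psd' or 'av'
    settings: dict       # bins, edf mode, cutoffs, kT, fixed params, seeds
    model_key: str
    estimates: dict
    errors: dict | None
    covariance: list | None
    cost: float
    loglik: float
    n_points: int
    K: int
    diagnostics: dict
    mcmc: dict | None = None
    comparison: dict | None = None
    spectrum: dict | None = None

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationReport":
        return cls(**json.loads(text))


def _default_model(method: str, tracking: bool) -> str:
    base = {"psd": "psd:lansdorp", "av": "av:lansdorp"}[method]
    return base + "+tracking" if tracking else base


def run_calibration(trajectory: Trajectory, method: str = "av", model: str | None = None,
                    bins: int = 3, edf: str = "empirical", kT: float = KT_ROOM,
                    fixed: dict | None = None, cutoffs: tuple | None = None,
                    tracking: bool = False, mcmc: bool = False, walkers: int = 32,
                    steps: int = 2500, seed: int = 0, compare_tracking: bool = False,
                    input_meta: dict | None = None, include_spectrum: bool = True,
                    ) -> tuple[CalibrationReport, FitResult, PosteriorSamples | None]:
    """Full chain: spectrum -> MLE fit -> diagnostics (-> MCMC), as a report.

    ``model=None`` selects the default zero-dead-time model for the method
    (with the tracking-error term if ``tracking``).  ``compare_tracking``
    additionally fits the +tracking variant and ranks the two by AIC.
    """
    if method not in ("psd", "av"):
        raise ValueError("method must be 'psd' or 'av'")
    model_key = model or _default_model(method, tracking)
    kind = model_key.split(":", 1)[0]
    if kind != method:
        raise ValueError(f"model {model_key!r} is incompatible with method {method!r}")
    est = (psd_welch(trajectory, bins) if method == "psd"
           else avar_overlapping(trajectory, edf=edf))
    spec = FitSpec(model=model_key, kT=kT, fixed=dict(fixed or {}), cutoffs=cutoffs)
    fit = fit_mle(est, spec)

    comparison = None
    if compare_tracking and not model_key.endswith("+tracking"):
        alt = fit_mle(est, FitSpec(model=model_key + "+tracking", kT=kT,
                                   fixed=dict(fixed or {}), cutoffs=cutoffs))
        comparison = compare_models([fit, alt])

    posterior = None
    mcmc_block = None
    if mcmc:
        posterior = mcmc_sample(est, spec, fit, walkers=walkers, steps=steps, seed=seed)
        mcmc_block = {
            "walkers": walkers, "steps": steps, "seed": seed,
            "acceptance_fraction": posterior.acceptance_fraction,
            "percentiles_15.8_84.2": {k: list(v) for k, v in posterior.percentiles.items()},
            "intervals": dict(posterior.intervals),
            "warnings": list(posterior.warnings),
        }

    report = CalibrationReport(
        schema_version=REPORT_SCHEMA_VERSION,
        software_version=__version__,
        input=dict(input_meta or {}, n_x=trajectory.n_samples, f_s=trajectory.f_s),
        method=method,
        settings={"bins": bins if method == "psd" else None,
                  "edf": edf if method == "av" else None,
                  "cutoffs": list(cutoffs) if cutoffs else None,
                  "kT": kT, "fixed": dict(fixed or {}), "seed": seed,
                  "noise_id": est.meta.get("noise_id")},
        model_key=model_key,
        estimates={k: float(v) for k, v in fit.params.items()},
        errors=({k: float(v) for k, v in fit.errors.items()} if fit.errors else None),
        covariance=(fit.cov.tolist() if fit.cov is not None else None),
        cost=fit.cost, loglik=fit.loglik, n_points=fit.n_points, K=fit.K,
        diagnostics=fit.diagnostics.as_dict(),
        mcmc=mcmc_block,
        comparison=comparison,
        spectrum=({"abscissa": est.abscissa.tolist(), "values": est.values.tolist(),
                   "shape": est.shape.tolist(), "model": fit.model_values.tolist(),
                   "residuals": fit.residuals.tolist()} if include_spectrum else None),
    )
    return report, fit, posterior
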