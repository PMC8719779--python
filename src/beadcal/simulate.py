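"""Langevin simulation of a trapped bead under video tracking.

A micron-scale bead held in a harmonic trap (magnetic or optical tweezers)
undergoes overdamped Brownian motion,

    kappa * x(t) + gamma * dx/dt = F_L(t),

with the Langevin force satisfying <F_L(t) F_L(t')> = 2 gamma kT delta(t-t').
This is an Ornstein-Uhlenbeck process with relaxation time tau_c = gamma/kappa
and stationary variance kT/kappa.  A video camera does not sample x(t)
instantaneously: each frame reports the average position over the exposure
time, and the tracking algorithm adds Gaussian localization noise on top.

The simulator reproduces both effects: it propagates the exact OU transition
density on a fine grid of ``oversample`` steps per frame (default 1000, i.e.
dt = 1/(1000 f_s)), block-averages each frame's fine steps to emulate a
zero-dead-time exposure (tau0 = tau_s), and finally adds independent
N(0, epsilon^2) tracking error per frame.

Units throughout the package: nm, s, Hz, pN, pN nm (so kT = 4.11 pN nm at
298 K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "KT_ROOM",
    "BOLTZMANN_PN_NM",
    "SimulationConfig",
    "Trajectory",
    "simulate_trajectory",
    "equipartition_kappa",
    "trap_force",
]

#: Boltzmann constant in pN nm / K.
BOLTZMANN_PN_NM = 1.380649e-2
#: Thermal energy at T = 298 K, pN nm.
KT_ROOM = 4.11


def thermal_energy(temperature_K: float) -> float:
    """kT in pN nm for an absolute temperature in kelvin."""
    if temperature_K <= 0:
        raise ValueError("temperature_K must be positive")
    return BOLTZMANN_PN_NM * temperature_K


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated bead trajectory.

    Attributes
    ----------
    n_samples : int
        Number of camera frames (output positions), >= 2.
    f_s : float
        Sampling rate in Hz.
    gamma : float
        Drag coefficient in pN s / nm.
    kappa : float
        Trap spring constant in pN / nm.
    kT : float
        Thermal energy in pN nm (default 4.11, T = 298 K).
    epsilon : float
        Tracking-error standard deviation in nm (>= 0; 0 disables it).
    oversample : int
        Fine integration steps per frame; the frame position is their mean,
        emulating a full-frame exposure tau0 = tau_s.
    seed : int
        RNG seed; identical configs give bit-identical trajectories.
    """

    n_samples: int
    f_s: float
    gamma: float
    kappa: float
    kT: float = KT_ROOM
    epsilon: float = 0.0
    oversample: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("n_samples", self.n_samples >= 2),
            ("f_s", self.f_s > 0),
            ("gamma", self.gamma > 0),
            ("kappa", self.kappa > 0),
            ("kT", self.kT > 0),
            ("epsilon", self.epsilon >= 0),
            ("oversample", self.oversample >= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid SimulationConfig field: {name}={getattr(self, name)!r}")

    @property
    def corner_frequency(self) -> float:
        """f_c = kappa / (2 pi gamma), Hz."""
        return self.kappa / (2.0 * math.pi * self.gamma)

    @property
    def relaxation_time(self) -> float:
        """tau_c = gamma / kappa, s."""
        return self.gamma / self.kappa


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled bead positions (nm) at rate ``f_s`` (Hz)."""

    positions: np.ndarray
    f_s: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 1 or pos.size < 2:
            raise ValueError("positions must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must all be finite")
        if self.f_s <= 0:
            raise ValueError("f_s must be positive")

    @property
    def n_samples(self) -> int:
        return self.positions.size

    @property
    def tau_s(self) -> float:
        """Sampling time 1/f_s, s."""
        return 1.0 / self.f_s

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.f_s


def _ou_exact(n: int, dt: float, tau_c: float, sigma2: float, rng: np.random.Generator) -> np.ndarray:
    """Exact Ornstein-Uhlenbeck sample path of length ``n`` at step ``dt``.

    Uses the transition density x(t+dt) = a x(t) + N(0, sigma2 (1 - a^2)),
    a = exp(-dt/tau_c), which is distributionally exact at any step size;
    x(0) is drawn from the stationary N(0, sigma2) so no burn-in is needed.
    """
    a = math.exp(-dt / tau_c)
    innov_sd = math.sqrt(sigma2 * -math.expm1(-2.0 * dt / tau_c))
    x0 = math.sqrt(sigma2) * rng.standard_normal()
    w = innov_sd * rng.standard_normal(n)
    # AR(1) recursion y[i] = a*y[i-1] + w[i] with y[-1] = x0, via an IIR filter
    y, _ = lfilter([1.0], [1.0, -a], w, zi=np.array([a * x0]))
    return y


def simulate_trajectory(config: SimulationConfig) -> Trajectory:
    """Generate a camera-sampled bead trajectory from the overdamped Langevin model.

    The OU process is propagated at dt = 1/(oversample * f_s); each block of
    ``oversample`` consecutive fine-step positions is averaged into one frame
    (exposure blur), and tracking error is added afterwards from the same
    seeded generator, so runs with epsilon = 0 and epsilon > 0 share the
    thermal noise stream for paired comparisons.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / (config.oversample * config.f_s)
    sigma2 = config.kT / config.kappa
    n_fine = config.n_samples * config.oversample
    fine = _ou_exact(n_fine, dt, config.relaxation_time, sigma2, rng)
    if config.oversample > 1:
        frames = fine.reshape(config.n_samples, config.oversample).mean(axis=1)
    else:
        frames = fine
    if config.epsilon > 0:
        frames = frames + config.epsilon * rng.standard_normal(config.n_samples)
    return Trajectory(positions=frames, f_s=config.f_s)


def equipartition_kappa(trajectory: Trajectory, kT: float = KT_ROOM) -> float:
    """Spring-constant estimate kT / var(x) from the equipartition theorem.

    This estimator is biased low whenever parasitic noise (tracking error,
    drift) inflates the variance, and also by exposure blur when tau_s is not
    much smaller than tau_c; the spectral fits in :mod:`beadcal.inference`
    correct for both.  Units: pN / nm.
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    var = float(np.var(trajectory.positions))
    if var == 0.0:
        raise ValueError("trajectory has zero variance; equipartition estimate undefined")
    return kT / var


def trap_force(kappa: float, L: float) -> float:
    """Upward trap force F = kappa * L (pN) on a tethered bead.

    ``L`` is the bead height above the surface (tether extension) in nm; the
    bead-tether system acts as an inverted pendulum, so the lateral spring
    constant converts directly to a vertical force.
    """
    if kappa < 0 or L < 0:
        raise ValueError("kappa and L must be non-negative")
    return kappa * L
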