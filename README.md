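# beadcal

Thermal-motion force calibration for single-molecule video-tracking
experiments (magnetic and optical tweezers).

In a tweezers experiment a micron-scale bead is held in an effectively
harmonic trap and its position is video-tracked at a frame rate `f_s`.  The
applied force follows from the trap spring constant, `F = κL`, so the whole
calibration problem reduces to estimating the drag coefficient `γ` (pN s/nm)
and the spring constant `κ` (pN/nm) from the bead's thermal motion.  Doing
this accurately from camera data requires care: the finite exposure time
low-pass filters the motion, sampling aliases above-Nyquist power into the
measured band, tracking errors add white noise, and the strongly skewed
sampling distributions of spectral estimates bias least-squares fits.

`beadcal` estimates `γ`, `κ` (and optionally the tracking-error amplitude
`ε`, in nm) with uncertainties from a *single* bead trajectory, by
maximum-likelihood fits of either

* the **Welch power spectral density** (Hann window, half-overlapping bins),
  fitted with the exact aliased + exposure-blurred Lorentzian

  `P(f) = (2kTγ/κ³) · (κ + 2γf_s sin²(πf/f_s) · sinh(κ/γf_s) / (cos(2πf/f_s) − cosh(κ/γf_s)))`,

* or the **octave-sampled overlapping Allan variance**

  `σ²_AV(τ) = (2kTγ/κ²τ) · (1 + (2γ/κτ)e^{−κτ/γ} − (γ/2κτ)e^{−2κτ/γ} − 3γ/2κτ)`,

  whose definition absorbs the zero-dead-time exposure blur automatically.

Both experimental estimates are Gamma-distributed around the theory curve
with a known per-point shape parameter η (the Welch bin count, or half the
equivalent degrees of freedom of each Allan point, determined from the
dominant power-law noise via lag-1 autocorrelation identification), so the
fit minimizes the Gamma negative log-likelihood
`ℓ = Σ η_k [ŷ_k/y_k + ln y_k]` rather than a least-squares cost.
Uncertainties come from the inverted Hessian of ℓ, optionally cross-checked
by ensemble MCMC (emcee).  Fit quality is reported as normalized residuals,
reduced χ², the support `F` (χ² CDF) with its p-value, and AIC for model
comparison (a rival model is preferred only at ΔAIC ≥ 4).

The package also contains the overdamped-Langevin simulator (exact
Ornstein–Uhlenbeck discretization with fine-step exposure averaging and
optional Gaussian tracking error) used to validate the whole pipeline.

Units everywhere: nm, s, Hz, pN, pN·nm (`kT = 4.11` pN·nm at 298 K).

## Worked example

```python
import numpy as np
import beadcal as bc

# simulate a 41 s trajectory: gamma = 1e-5 pN s/nm, f_c = 5 Hz
cfg = bc.SimulationConfig(n_samples=4096, f_s=100.0, gamma=1e-5,
                          kappa=2*np.pi*1e-5*5.0, seed=42)
traj = bc.simulate_trajectory(cfg)

report, fit, _ = bc.run_calibration(traj, method="av")
print(fit.summary())
```

prints

```
model av:lansdorp: N_y=11, K=2
  gamma = 1.00857e-05 +/- 3.88e-07
  kappa = 0.00031299 +/- 6.36e-06
  chi2_nu = 1.732 (nu=9), support F = 0.924, p = 0.076, AIC = 140.1
```

i.e. the drag coefficient is recovered to 0.9% and the spring constant
(truth 3.1416e-4) to 0.4%, each well within its standard error; χ²ν ≈ 1.7
over 9 degrees of freedom (support 0.92, p = 0.08) is unremarkable for a
single trajectory.  The force on a bead tethered at L = 700 nm would be
`bc.trap_force(fit.params["kappa"], 700.0)` ≈ 0.219 pN.

The same workflow is available from the shell:

```sh
beadcal simulate --n 4096 --fs 100 --gamma 1e-5 --kappa 3.14e-4 --seed 42 --out traj.csv
beadcal calibrate traj.csv --method av --out report.json
beadcal calibrate traj.csv --method psd --bins 3 --compare-tracking --out report2.json
beadcal benchmark --fc 0.2,1,5,20,100 --replicates 100 --out bias.csv
```

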