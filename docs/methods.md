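# Methods

This note records the model, the estimator conventions, the numerical
choices, and the known limitations of `beadcal`, at the level of detail a
user needs to judge what a calibration (or a passing test suite) does and
does not establish.

## Physical model

The bead is an overdamped Ornstein–Uhlenbeck process: `κx + γẋ = F_L(t)`
with white thermal force `⟨F_L(t)F_L(t')⟩ = 2γkT δ(t−t')`.  Two derived
scales organize everything: the corner frequency `f_c = κ/(2πγ)` and the
relaxation time `τ_c = γ/κ`.  Hydrodynamic memory (relevant below ~1e-4 s)
and bead–surface coupling are outside the model; at video rates they are
negligible, and a known `γ` can always be fixed during fitting instead.

The measured record differs from `x(t)` in three ways, all in closed form
in `beadcal.models`:

* **Exposure blur.** A zero-dead-time camera reports the boxcar average over
  `τ0 = τ_s = 1/f_s`; in power this is `I(f) = sinc²(fτ0)`.
* **Aliasing.** Sampling folds `f + nf_s` onto `0 < f < f_s/2`; the blurred,
  aliased Lorentzian sums exactly to the `sinh/(cos − cosh)` closed form
  (`psd_closed_form`).  A dead-time variant (blur-free aliased Lorentzian,
  `psd:lorentzian-aliased`) is provided for cameras with `τ0 ≪ τ_s`, and a
  direct lattice sum (`psd_aliased_sum`) serves as the oracle for both and
  handles general `τ0`.
* **Tracking error.** Gaussian localization noise of standard deviation `ε`
  adds `ε²/f_s` to the PSD and `ε²τ_s/τ` to the Allan variance
  (`*+tracking` model variants).

The Allan-variance curve `av_thermal` rises as `2kTτ/(3γ)` (free diffusion),
peaks at `τ ≈ 1.89 τ_c`, and decays as `2kTγ/(κ²τ)` (trap-dominated).  The
printed form of its bracket is typographically ambiguous in parts of the
literature; the coefficients used here, `1 + (2/u)e^{−u} − (1/2u)e^{−2u} −
3/(2u)` with `u = τ/τ_c`, are fixed uniquely by requiring both asymptotes
and the 1.89 τ_c maximum (the series check is in the `av_thermal`
docstring).

PSD convention: all densities are two-sided, reported on positive
frequencies, so the full-line integral of the Lorentzian is `kT/κ` and
white noise of variance `ε²` sits at `ε²/f_s`.  A dedicated test pins this.

## Estimators

**Welch PSD** (`psd_welch`): M half-overlapping bins of length
`L = ⌊2N_x/(M+1)⌋` (trailing samples discarded), per-bin mean removal
(switchable; suppresses DC leakage from drift), Hann window
`w_j = √(8/3)·sin²(πj/L)` (the √(8/3) implements the 8/3 power correction),
periodograms `|FFT|²/(f_s Σw²)` averaged per frequency, DC dropped, Nyquist
kept.  Default M = 3.  Each point is treated as Gamma with shape `η = M`.

**Overlapping Allan variance** (`avar_overlapping`): octave bin lengths
`m = 2, 4, …, 2^⌊log2(N_x/2)⌋`; at each `m`, one half the mean squared
difference of adjacent `m`-sample window means, start indices sliding by
one sample (`M = N_x − 2m + 1` pairs separated by `m`), computed via
cumulative sums.  Shape `η = ν/2` with `ν` the equivalent degrees of
freedom.

**Equivalent degrees of freedom.** The dominant power-law class at each
observation time is identified by the lag-1 autocorrelation method on the
`m`-decimated record (`δ = r1/(1+r1)`, differencing while `δ > 1/4`, up to
twice; `α = −round(2δ) − 2·#diffs`, clamped to [−2, 2]; classes steeper
than −2 are labelled drift and use the −2 kernel).  Points with
`N_x/m < 32` inherit the last reliable class; if no point is reliable the
code warns and falls back on `ν = N_x/m − 1` (also available explicitly
with `edf='approx'`).  Given the class, `ν` is computed *exactly* for
Gaussian power-law noise from the covariance of the window-difference
statistic: `1/ν = (1/M) Σ_{|j|<M} (1−|j|/M) ρ(j)²` where `ρ` follows from
the closed-form autocorrelation of the Haar-type window filter convolved
with the generalized noise autocovariance (`_edf.py`).  No asymptotic
tables or truncations are involved; the test suite validates the result
against a Monte-Carlo oracle (empirical `2E[v]²/Var[v]` of simulated pure
power-law noise) at a few percent for the white, white-phase, flicker and
random-walk classes.  Two findings worth knowing:

* the common approximation `ν = N_x/m − 1` *underestimates* ν for
  white-like noise (as usually claimed) but *overestimates* it by ~5–25%
  for random-walk-like noise, where overlapping adds almost no information;
* the flicker kernels use a Nyquist-band-limited logarithmic
  regularization (`R(0) − R(k) → ln k + γ_E + ln π`) and are accurate to a
  few percent, which is ample for their role as likelihood weights.

## Inference

The Gamma negative log-likelihood `ℓ = Σ η_k[ŷ_k/y_k + ln y_k]` is
minimized over the *logarithms* of the free parameters (positivity for
free) with Nelder–Mead (`xatol = 1e-8`, `fatol = 1e-10`, one restart from a
perturbed point if the first attempt fails).  Initial guesses are closed
form: for the PSD, `κ0` from the equipartition band power and `γ0` from the
half-plateau frequency; for the AV, from the peak height (`AV_max =
0.3811·kT/κ`) and location (`1.89 τ_c`) when the maximum is interior, else
from the two asymptotes.  `ε` enters only through `*+tracking` models and
is counted in K only when free.

Standard errors invert the central-difference Hessian of ℓ in log space
(step 1e-3; at 1e-5 the float rounding of an O(1e3) cost would swamp the
second difference) and map to natural units by the delta method.
Non-positive-definite Hessians raise/flag rather than pseudo-invert.  The
optional MCMC cross-check (emcee, default 32 walkers × 2500 steps, 25%
burn-in, vectorized log-probability, seed required) reports 15.8/84.2
percentile half-widths.

Diagnostics follow the Gamma model: `Δ_k = (ŷ_k − y_k)√η_k / y_k`,
`χ²ν = ΣΔ²/(N_y − K)`, support `F = P(ν/2, χ²/2)` together with the
p-value `1 − F` (both are always reported; conventions in the literature
disagree about which orientation to call "support"), and
`AIC = 2K − 2 ln L̂` with the *full* Gamma density (constants included) so
AICs are comparable across models; ΔAIC ≥ 4 declares a winner.

## Simulator

`simulate_trajectory` uses the exact OU transition
`x(t+δt) = x e^{−δt/τ_c} + N(0, (kT/κ)(1 − e^{−2δt/τ_c}))` — correct at any
step — with `x(0)` stationary (no burn-in), at `δt = 1/(oversample·f_s)`
(default 1000 fine steps per frame); frames are block means (boxcar
exposure), and tracking noise is drawn *after* the thermal stream so paired
`ε = 0` / `ε > 0` runs share thermal noise.  What the generator does *not*
emulate: hydrodynamic memory, drift, line-frequency interference,
non-Gaussian tracking artifacts, dead time.  Passing tests therefore
establish correctness of the estimators under the stated model, not
robustness to every laboratory pathology; the cutoff and
reference-spectrum facilities exist precisely for data that violate the
model at the band edges.

## Validation choices and problem sizes

The benchmark (`beadcal.benchmark`, `scripts/acceptance.py`) simulates
`N_x = 4096`, `f_s = 100` Hz, `γ = 1e-5` pN·s/nm and sweeps `f_c`, deriving
`κ = 2πγf_c`; at the mid-band point `f_c = 5` Hz the acceptance script uses
600 replicates (median bias is then determined to ~±0.3%), and the test
suite 1000.  Test-suite simulation sizes (replicate counts, oversampling
factors of 25–200 in tests that do not probe exposure fidelity) were chosen
as the smallest ensembles whose pass/fail state is stable under reseeding.
The calibration study for uncertainty coverage and the χ²/support
distribution checks run on Gamma-sampled synthetic spectra around the
theory curve — the "correct model" construction — because that is the
hypothesis the likelihood machinery actually encodes (see Limitations).

## Known limitations

* **Reported σ is slightly optimistic for trajectory fits.**  The
  likelihood treats spectrum points as independent Gamma variates.  Welch
  bins are correlated by the Hann window (adjacent-bin power correlations
  4/9 and 1/36, an information loss factor of 35/18, i.e. true standard
  errors ≈ 1.4× the reported ones), and overlapping AV points share data
  (worse for κ, whose information sits at long τ).  Point estimates are
  unaffected (the estimating equation stays unbiased), and the MCMC option
  inherits the same likelihood, so this is a property of the method family,
  not of the sampler.  On exactly-Gamma data the 1σ coverage is nominal
  (68%), which is what the uncertainty-calibration tests pin.
* **Low corner frequencies** (`f_c·N_x/f_s ≲ a few`) leave κ poorly
  constrained; **high corner frequencies** (`f_c ≳ f_s/8`) leave γ poorly
  constrained and correlated with κ — fix γ to a known value there
  (`fixed={'gamma': …}` or `--fix gamma=…`).
* The AV model assumes zero dead time; with substantial dead time use the
  PSD with the `psd:lorentzian-aliased` model instead.
* The lag-1 classifier assigns one dominant class per observation time;
  mixed-noise crossover regions are assigned the nearer pure class, which
  perturbs only the likelihood weights, not the model curve.
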