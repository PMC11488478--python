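# Methods

## Data model and units

All spectra are `SqwMap` objects: S(q, ω) on ascending q bin centers
(Å⁻¹, constant integration step Δq) and a uniform ω grid (meV), with a
per-bin 1σ uncertainty.  Energies are meV internally; CLI options accept
μeV (resolutions are conventionally quoted in μeV, quasi-elastic widths
in meV) and convert once at the boundary.  Non-positive σ entries are
floored at 10⁻¹² of the map maximum with a logged warning so weighted
fits never receive infinite weights.  Window integrals (`integrate_window`)
are trapezoidal with partial-bin clipping by linear interpolation at the
window edges; uncertainties propagate through the trapezoid weights in
quadrature, which makes the integral exactly additive over adjacent
windows and testable against closed forms.

## Polarization algebra

The separation uses the standard nuclear-spin-incoherent result: 1/3 of
the spin-incoherent intensity appears non-spin-flip and 2/3 spin-flip,
while coherent (and isotope-incoherent) scattering is entirely
non-spin-flip.  Hence S_inc = (3/2)·sf, S_coh = nsf − (1/2)·sf,
S_tot = nsf + sf.  The coefficients are overridable
(`SeparationCoefficients`) for isotopic-incoherence variants.  A finite
flipping ratio R mixes the channels as observed = M·ideal with
M = [[R, 1], [1, R]]/(R+1); `correct_flipping_ratio` applies the exact
2×2 inverse with linear error propagation.  The kinematic k_i/k_f factor
√(E_i/(E_i−ω)) (energy-loss convention) is applied before separation by
default.  Negative intensities produced by counting noise after
separation or subtraction are deliberately preserved: flooring them would
bias downstream χ² statistics.

## Reduction

Empty-can subtraction first, on every spectrum; then the
volume-fraction-weighted buffer subtraction
S_protein = S_solution − (1−ϕ)·f·S_buffer with ϕ = c·v̄
(mg/mL × mL/g × 10⁻³) and f a scalar beam-attenuation factor (default
1.0, config-exposed).  v̄ defaults to 0.73 mL/g, a typical
globular-protein value, not a measured one.  The hydration-layer volume
fraction is estimated from a spherical-shell construction,
ϕ_hyd = (c·N_A/M_w)·(4π/3)·[(r+d)³ − r³], with the concentration
converted to g/Å³; a result ≥ 1 raises, since it almost always signals a
unit error.

## Fitting

Per-q weighted least squares (`scipy.optimize.least_squares`, TRF, tight
tolerances) of two resolution-convolved models:

* EISF model: amp·[a₀·δ + (1−a₀)·L(γ)] ⊗ R + (b₀ + b₁ω).  The δ term is
  convolved analytically — it *is* the resolution lineshape — avoiding
  finite-bin artifacts.
* Two-Lorentzian model: [amp₁·L(γ₁) + amp₂·L(γ₁+γ₂)] ⊗ R + (b₀ + b₁ω).
  The second width is γ₁+γ₂ because Lorentzian HWHMs add under
  convolution; the internal process rides on the global one.

Convolution is discrete linear convolution on the uniform ω grid,
multiplied by the grid spacing and sliced so the kernel's ω = 0 sample
stays aligned; a unit-area kernel then preserves spectral area and maps a
δ exactly onto the resolution lineshape.  Bounds: a₀ ∈ [0, 1],
γ ∈ [10⁻⁴, 10] meV, amplitudes ≥ 0, background free.  Determinism comes
from a fixed multi-start grid over the quasi-elastic width — a decade
bracketing the resolution FWHM (FWHM/3, FWHM, 3·FWHM for the EISF model;
a 2×2 width grid for the two-Lorentzian model) — keeping the best final
χ², ties broken by the smaller γ₁.

Confidence intervals are the square roots of the diagonal of the
**unscaled** covariance (JᵀJ)⁻¹ of the σ-normalized residuals: the σ are
true counting errors, so no χ² rescaling is applied at the spectrum
level, and the 1σ intervals are calibrated (coverage ≈ 68%, verified by
simulation).  Reduced χ² = χ²/(n−p) throughout.

## Width-vs-q analysis

`analyze_widths` fits Γ(q) three ways: linear in q² (free intercept by
default, with the through-origin variant reported alongside, since the
experimental plots imply near-zero intercepts but the constraint is never
stated), jump diffusion Γ = ħDq²/(1+Dq²τ), and an inverse-variance
weighted constant.  Slopes convert to diffusion coefficients via
ħ = 0.6582119 meV·ps (Å²/ps → Å²/ns ×1000).  A negative diffusion
estimate is reported as 0 with its uncertainty (the raw value is kept in
`d_eff_raw`).  Unlike the per-spectrum fits, the across-q fits scale
parameter errors by √max(red χ², 1): deviations of Γ(q) from any simple
q law are dominated by systematics (e.g. residual coherent
contamination), so the quoted uncertainty must reflect the scatter of
the points, never dropping below the statistical floor.

## Model-selection ladder

Simplest model first: the EISF model is accepted iff its median reduced
χ² is below 2 **and** its Γ(q) slope against q² is consistent with 0 at
2σ (the signature of purely local, confined dynamics — a q²-linear width
from this model is unphysical for internal motion and forces
escalation).  Cases where exactly one criterion fails are flagged
ambiguous but resolved by the same rule.  A BIC comparison between the
two models is reported as a cross-check only; it never overrides the
ladder, and it stands in for a full Bayesian model comparison, which is
out of scope here.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
with ground truth retained:

* **Incoherent protein signal**: per q,
  amplitude·[A₀(q)·L(Γ_glob(q)) + (1−A₀(q))·L(Γ_glob(q)+Γ_int)].  With
  no global diffusion the first term is an elastic line, realized as its
  full weight in the single ω = 0 bin pre-convolution (grid-exact,
  avoiding a zero-width Lorentzian).  Default A₀(q) = p + (1−p)·[3j₁(qR)/(qR)]²
  (immobile fraction p = 0.3, sphere radius R = 2.3 Å — a plausible
  side-chain confinement geometry), Γ_int = 0.064 meV and D = 0 (internal
  dynamics only, the regime the separated incoherent data exhibit); the
  jump-diffusion generator Γ = ħDq²/(1+Dq²τ) is available with D and τ
  config-exposed.
* **Coherent contribution**: S(q) is a Gaussian bump centered at
  1.95 Å⁻¹ (D₂O-like structure-factor maximum) of width 0.25 Å⁻¹, times
  a quasi-elastic Lorentzian.  The width keeps the bump localized at
  high q — coherent intensity is low and flat below q ≈ 1.2 Å⁻¹ and
  dominant near the maximum, which is the observed morphology this
  scenario emulates and the property that makes q-range truncation an
  effective mitigation.  The protein's post-subtraction remnant
  (hydration layer) uses peak amplitude 1.5× the incoherent weight and
  HWHM 0.10 meV; the buffer's coherent line is slightly faster
  (0.15 meV).
* **Buffer**: broad residual-¹H incoherent Lorentzian (amplitude 0.25,
  HWHM 0.3 meV) plus the coherent bump.  By default the buffer's
  coherent amplitude is *solved* so that the windowed coherent/incoherent
  S(q) ratio crosses 0.5 exactly at q* = 1.15 Å⁻¹, using the analytic
  Voigt profile (Lorentzian ⊗ Gaussian resolution) and adaptive
  quadrature — an independent route from the pipeline's discrete
  integrals.
* **Instrument**: Gaussian resolution kernels (FWHM 65.77 μeV default,
  30.8 μeV alternative), flipping ratio 20 (realistic
  supermirror + flipper optics), and Poisson noise with 10⁴ expected
  counts at the elastic peak.  Channels are nsf = coh + inc/3,
  sf = 2·inc/3, mixed by the finite flipping ratio, with σ = √counts.
  The measured solution contains protein + (1−ϕ)·f·buffer + can, the
  measured buffer contains buffer + can; each measurement draws from an
  independent stream spawned off the run seed, so runs are bitwise
  reproducible.

What the generator does **not** emulate: multiple scattering, detector
geometry and path-length effects, time-dependent analyzer efficiency,
H/D exchange, and any realistic S_coh(q, ω) lineshape beyond a single
Lorentzian.  Passing tests therefore demonstrate the correctness of the
analysis chain and the *mechanism* of coherent contamination, not
instrument-level reduction fidelity.

## Default study conditions

q = 0.45–1.95 Å⁻¹ with Δq = 0.1 Å⁻¹ (16 bins); ω = ±1.5 meV with
5 μeV steps (601 points); elastic integration window 250 μeV for the
65.77 μeV resolution (80 μeV pairs with the 30.8 μeV setting; the
mapping of windows to resolutions is ambiguous in its source and is
config-overridable).  Diagnostics threshold 0.5.  The q-limited refit
truncates at the ratio-rule cutoff and compares the truncated total
linear-q² diffusion coefficient with the full-range incoherent one at
combined 2σ — the diffusion coefficient, not Γ̄, is the quantity the
truncation comparison is about, since the contamination signature is the
spurious q² slope.

## Numerical choices and edge cases

* Logistic turning point: the four-parameter logistic
  a + b/(1+e^{−k(q−q₀)}) is fitted to the sample/buffer ratio; "where
  the slope begins to increase" is the maximum of the second derivative,
  q₀ − ln(2+√3)/k for a rising limb.  The ratio in the full scenario
  *falls* toward its coherent-dominated plateau, and for a falling limb
  the slope begins to increase at the inflection q₀ itself; the
  implementation is orientation-aware.  If the fit fails, the maximum
  discrete second difference is used and flagged.
* 0.5-rule: conservative first-crossing semantics with linear
  interpolation between the bracketing bins; a ratio that never exceeds
  the threshold returns the grid maximum flagged "never-exceeds", and a
  first bin already above it returns an undefined cutoff.
* Convolution requires grid uniformity to 1 part in 10⁶; kernels are
  normalized to unit trapezoidal integral on their grid.
* Lorentzian tails are heavy: truncated-grid integrals carry O(γ/ω_max)
  missing mass, so normalization tests compare against the windowed
  arctan/Voigt closed forms rather than asserting unit area on finite
  grids.

## Known limitations

The general n-Lorentzian fit (beyond two components) is typed but not
implemented.  Raw event-data reduction (NeXus/Mantid workspaces),
magnetic/xyz polarization analysis, multiple-scattering corrections and
global multi-q fitting are out of scope.  The two-Lorentzian amplitudes
are free per q (no cross-q constraint).  Problem sizes in the test suite
(one pipeline realization, 100 fit replicates, 10 reduction replicates)
were chosen as comfortable desk-scale statistics for the properties
being demonstrated.
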