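# Methods

## Physical model

The package models the initial photoacoustic pressure of a uniaxial,
dichroic, scattering-free absorber illuminated from above with linearly
polarized light at angle θ:

```
p(r, θ) = Γ η_th F(r, θ) μa(r, θ)
μa(r, θ) = μ̄a(r) + (Δμa(r)/2) cos 2(θ − ϕ(r))
F(r, θ)  = F0 exp(−∫ μa(r', θ) dℓ)          (ballistic Beer–Lambert decay)
```

μ̄a is the mean of the ordinary and extraordinary absorption coefficients,
Δμa = μa,o − μa,e the linear dichroism, and ϕ the optic-axis (fiber)
orientation, a director with period 180°. Light travels straight down one
lateral column at a time; refraction and scattering are not modelled (an
optional effective-attenuation term μs' can be added to the fluence decay
only). The polarization orientation is assumed preserved along the path,
which is appropriate for the dichroism and birefringence magnitudes of
tendon-like tissue.

Expanding the dichroic part of the fluence exponential to first order
factorizes the pressure into a product of two cosines:

```
p = p̄ (1 + α cos(2θ − 2ψ)) (1 + β cos(2θ − 2ϕ)),   β = Δμa / (2 μ̄a)
α e^{-2iψ-iπ} = ∫ (Δμa/2) e^{-2iϕ} dℓ
```

α ≥ 0 and ψ are the amplitude and phase of the *accumulated* fluence
modulation. The truncated expansion formally carries a minus sign; we keep
α nonnegative and absorb the sign into ψ, which yields the homogeneous-case
counter-phase relation ψ = ϕ + 90°. The product expands into DC,
fundamental (cos 2θ) and second-harmonic (cos 4θ) components; the
fundamental observables used by the estimator are

```
ξ  = √(α² + β² + 2αβ cos 2(ϕ − ψ))                    (normalized amplitude)
η  = atan2(α sin 2ψ + β sin 2ϕ, α cos 2ψ + β cos 2ϕ)  (doubled-angle phase)
```

η behaves like a sigmoid between the asymptotes 2ϕ (absorption-dominated,
α ≪ β) and 2ψ (fluence-dominated, α ≫ β). In a homogeneous medium α grows
linearly while β is constant, so η flips by 180° (doubled angle; 90° in
orientation) where α crosses β — at depth ≈ 1/μ̄a — and the amplitude
vanishes there because the two modulations are in exact counter-phase.

## Demodulation

Per pixel, the sweep is demodulated by FFT over an integer number of 180°
modulation periods. The default protocol (0°–1080° in 10° steps, 109
acquisitions) duplicates its start angle modulo 180° at the final sample, so
that sample is dropped (108 samples, fundamental at bin 6); an exact
integer-period window makes the single-bin estimates leakage-free, which we
prefer over windowing at these small sample counts. Amplitude/phase
conventions: a component is A·cos(2θ − δ) with δ stored in (−180°, 180°];
the H2 phase is stored halved (comparable to ϕ + ψ as a director). p̄ is
estimated by the DC bin, accepting its O(αβ/2) product bias; the bias is
below ~4% even at the deepest simulated fluence modulations and is
documented rather than corrected. Recorded pulse energies divide each frame
before demodulation (`energy_correct`), exactly inverting the simulated
multiplicative jitter.

## Inversion

Per A-line (surface → depth), the estimator minimizes

```
ε = wrap(η_obs − η_model)² + (ξ_obs − ξ_model)²
```

(phase residual wrapped on the doubled-angle circle, in radians, so both
terms share a common scale — the source model does not state a wrapping
rule, so we fix one) over (α, ψ, ϕ) with β held fixed per column. This is
2 observables for 3 unknowns; the closure is physical:

* **Surface rule.** At the first unmasked pixel the fluence modulation is
  negligible: ϕ ← η/2, β ← ξ, α ← 0, ψ ← ϕ + 90°. β stays fixed for the
  column (`per-column-surface`, the default, tolerates lateral
  inhomogeneity; `fixed-from-surface` uses the median across columns).
* **Fluence continuity and seeding.** The accumulated fluence vector
  α·e^{2iψ} evolves smoothly, so each depth is seeded by linear
  extrapolation of that vector from the previous fits (scaled across masked
  gaps), and (α, ψ) are box-constrained around the seed
  (`continuity_alpha` = 0.01/step, `continuity_psi` = 15°/step, both scaled
  by the gap length). With ϕ held, the remaining two-unknown problem has the
  closed-form solution F = V − β e^{2iϕ} (V = ξ e^{iη} the observed vector);
  projected into the boxes it seeds the bounded quasi-Newton fit (L-BFGS-B
  with analytic gradients, stopping at projected-gradient optimality 1e−6;
  any local constrained minimizer reaching that optimality is acceptable).
* **ϕ continuity.** ϕ is constant inside a layer, so its per-step bound
  `continuity_phi` defaults to 2° — enough to absorb slow model error (e.g.
  a drifting dichroism ratio), far below the smallest layer contrast the
  detector must resolve (30°), and not widened across masked gaps.
* **Cancellation (α ≈ β).** When the extrapolated α is within
  `alpha_beta_tie_tol` (10% relative) of β — or when the data themselves
  imply it, |V − β e^{2iϕ_prev}| ≈ β — the pixel sits at the cancellation
  point: the phase is ill-determined and any 180° flip belongs to the
  fluence term, so ϕ is held fixed. The tolerance band widens with the
  measurement noise (see below).
* **Zero crossing of the fluence vector.** If α returns to ≈ 0 below the
  surface the accumulated vector has passed through the origin and ψ
  advances by 90°; the vector extrapolation handles this automatically, and
  an explicit ψ+90° candidate covers the start-up case with no increment
  history.
* **Layer change.** Sudden *simultaneous* variations of η and ξ
  (`abrupt_eta_thresh` = 60° doubled-angle, `abrupt_xi_relthresh` = 0.2,
  judged against both the predicted evolution and the last valid
  observation) mark a change of ϕ. The branch is taken only when the
  ϕ-held continuity fit still misses the observation by those same margins;
  then ϕ is re-seeded from the direction of V minus the extrapolated fluence
  vector — the remainder is the local dichroism term β e^{2iϕ} — and
  released. Seeding from η/2 alone is wrong at depth, where η is a
  fluence–absorption mixture.
* **Noise-aware significance.** With a background noise level available,
  the per-pixel ξ uncertainty σ_ξ = σ_bg / p_mean converts every abruptness
  threshold into `max(threshold, rose_k·σ)` (and an analogous phase
  uncertainty σ_ξ/ξ); a variation must be both large and statistically
  significant to trigger a branch, so noise cannot fake a layer change.
  All these guards reduce to the bare thresholds in the noiseless limit.

Pixels whose fundamental amplitude is below `rose_k` (= 5) background
standard deviations are masked before estimation (Rose detectability
criterion), with one exception: the amplitude minimum of a masked run whose
bracketing detectable phases differ by ≈ 180° (doubled angle) is retained as
an α = β cancellation point. The flip is judged between the nearest
*detectable* neighbors because the dip spans several cells at realistic
noise and the phases inside it are noise. The background σ comes from a
declared tissue-free region (the std of its H1 amplitudes) or an explicit
value. After estimation, masked orientations are filled by linear
interpolation along depth on doubled-angle unit vectors (circular-safe, so
89° and −89° interpolate near ±90°), with nearest-fill at column ends.

Failure of the optimizer at a pixel masks that pixel and the march continues
from the last good state. Columns are independent; there is no lateral
regularization.

## Synthetic data: what it emulates, and what not

`acquire_sweep` emulates the acquisition protocol of the physical
experiment: polarization swept 0°–1080° in 10° steps (109 acquisitions,
three half-wave-plate revolutions), 40-frame averaging, 5 mJ/cm² surface
fluence, per-pulse energy recording. Averaging is simulated as noise
variance reduction (σ/√n on a single draw) — distributionally identical to
storing frames. Pulse-energy jitter is lognormal with mean exactly 1 so
energies are always positive; the CV default used in the noise studies is
2%, a typical pulsed-laser stability figure (the source experiment recorded
but did not quantify its fluctuation). Additive frame noise is white
Gaussian; `calibrate_additive_sigma` solves analytically (via the Rayleigh
statistics of a noise-only H1 amplitude) for the per-frame σ that puts the
surface H1 amplitude at a requested multiple — 20 in the studies — of the
background amplitude std.

Preset geometries: `single` (one homogeneous tendon, 3.2 mm), and two
stacked presets (two 1.6 mm tendons, relative orientation 90° or 30°,
optional water gap). Default optics: Δμa/μ̄a = 0.1 (the measured tendon
dichroism ratio at 532 nm); the absolute μ̄a = 5 cm⁻¹ is an assumption —
the source experiment never states it — chosen so the predicted phase-jump
depth 1/μ̄a = 2 mm sits inside the 3.2 mm imaging depth. All defaults are
config-overridable. Default grid: 0.1 mm axial × 0.5 mm lateral cells
(0.36 cm × 1.6 cm).

Not emulated: acoustic propagation, transducer bandwidth and beamforming;
speckle; optical scattering and depolarization; refraction/reflection losses
at water gaps (a gap only zeroes absorption). Passing tests therefore
demonstrate the estimator's correctness under the stated signal model, not
its performance against acoustic artifacts or strongly scattering tissue.

## Numerical choices

* Path integrals: cumulative trapezoid over [0, z_0, …, z_n] at grid
  resolution, with the surface sample equal to the first cell's absorption;
  tests validate against 1000-point quadrature.
* Angles: orientations live in (−90°, 90°], doubled-angle phases in
  (−180°, 180°]; all phase residuals and interpolation are circular.
  Internal ψ/ϕ tracks are kept unwrapped during the march.
* Degenerate inputs: exact cancellation (ξ = 0) flags the model phase
  indeterminate (NaN); water pixels carry NaN orientation and are excluded
  from every statistic; columns with no detectable pixel stay empty.
* Determinism: all randomness flows from one integer seed; rerunning any
  stage with the same config and seed reproduces estimate maps bit-exactly.

## Problem sizes

The bundled studies use a 36×16 or 36×32 grid with the 109-frame sweep per
phantom; the orientation-accuracy study pools 13 such phantoms
(−90°…90° in 15° steps). These sizes give a few thousand estimated pixels
(statistically stable pooled RMSE) while keeping any single study in the
seconds range on one CPU.

## Known limitations

* An orientation change concealed *entirely* inside a masked run (e.g. a
  30° rotation behind a wide water gap) can be absorbed by the fluence
  track — from a single re-emerging pixel the two explanations are
  indistinguishable; perpendicular changes are still recovered because the
  amplitude inconsistency is decisive.
* β is assumed constant per column; strongly depth-varying dichroism ratio
  violates the closure and will bias α, ψ before it biases ϕ.
* The truncated (product-form) fluence is second-order accurate in Δμa;
  simulations in `exact` mode with large accumulated dichroic integrals
  (≳ 0.3) depart from the estimator's model.
* Orientation is resolved only in the plane perpendicular to the beam, as a
  director (no 3-D fiber inclination).
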