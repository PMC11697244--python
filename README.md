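# dspa — dichroism-sensitive photoacoustic orientation imaging

`dspa` simulates and analyzes **dichroism-sensitive photoacoustic (DS-PA)**
measurements of fibrous tissue, and recovers the depth-resolved fiber
(optic-axis) orientation map from polarization-swept B-scans.

Collagen-rich tissue such as tendon absorbs linearly polarized light
anisotropically (linear dichroism): for polarization angle θ the absorption
coefficient is

```
μa(r, θ) = μ̄a(r) + (Δμa(r)/2)·cos 2(θ − ϕ(r))
```

where ϕ is the local fiber orientation, μ̄a the mean absorption and Δμa the
dichroism. Sweeping θ therefore modulates the photoacoustic pressure
`p = Γ η_th F μa` sinusoidally, and at the tissue surface the phase of that
modulation reads out ϕ directly. At depth, however, the fluence F has itself
accumulated a polarization modulation along the beam path; to first order

```
p = p̄ · (1 + α cos(2θ − 2ψ)) · (1 + β cos(2θ − 2ϕ)),      β = Δμa / (2 μ̄a)
```

with (α, ψ) the amplitude and phase of the accumulated fluence modulation.
In a homogeneous sample ψ = ϕ + 90° and α grows linearly with depth, so the
measured fundamental-harmonic phase η flips by 90° (orientation domain) at
the depth where α overtakes β — approximately the inverse attenuation
1/μ̄a — even though the fibers never change direction. `dspa` implements
the forward model of this effect and the depth-sequential constrained
inversion that separates the fluence term from the absorption term, so the
true ϕ(z) can be recovered through the flip and through stacked layers of
differently oriented tissue.

Who it is for: researchers developing polarization-resolved photoacoustic
imaging who need a faithful in-silico testbed — phantoms, acquisition
simulation with realistic noise, harmonic demodulation, the constrained
estimator, and orientation statistics — in one package.

## What is inside

| module | contents |
| --- | --- |
| `dspa.phantom` | layered dichroic tissue phantoms, tendon presets, YAML configs |
| `dspa.forward` | anisotropic absorption, exact/truncated fluence, pressure maps, noisy polarization-sweep acquisition, SNR calibration |
| `dspa.spectral` | pulse-energy correction, per-pixel FFT demodulation into DC/H1/H2, closed-form H1 observables |
| `dspa.estimate` | Rose-criterion masking (with the cancellation-point exception), the squared-residual objective, the depth-sequential constrained fit, circular interpolation of masked areas |
| `dspa.report` | orientation histograms, circular statistics, director RMSE, depth-profile figures |
| `dspa.cli` | `dspa simulate / analyze / recover / report` pipeline over HDF5 containers |

## Worked example

Simulate a single tendon oriented at 30°, imaged with the default protocol
(polarization swept 0°–1080° in 10° steps → 109 acquisitions, 40-frame
averaging, 5 mJ/cm² surface fluence), with additive noise calibrated so the
surface fundamental-harmonic amplitude is 20× the background noise, then run
the full recovery:

```python
import numpy as np
from dspa import (FitConfig, SweepConfig, NoiseConfig, acquire_sweep, tendon_presets,
                  polarization_spectrum, energy_correct, estimate_image, rose_mask,
                  interpolate_masked, orientation_histogram, angular_error)
from dspa.forward import calibrate_additive_sigma

phantom = tendon_presets("single", phi1=30.0)
sweep = SweepConfig()                      # 0-1080 deg, 10 deg steps, 109 frames
sigma = calibrate_additive_sigma(phantom, sweep, target_surface_snr=20.0)
noise = NoiseConfig(additive_sigma=sigma, energy_jitter_cv=0.02, seed=7)

stack = acquire_sweep(phantom, sweep, noise)
spectral = polarization_spectrum(energy_correct(stack))
cfg = FitConfig(noise_sigma_source=((34, 36), (0, 32)))   # water rows = background
mask = rose_mask(spectral, cfg)
est = estimate_image(spectral, mask, cfg)
est.phi_interp = interpolate_masked(est.phi_map, est.mask)

summary = orientation_histogram(est.phi_map, est.mask)
rmse = angular_error(est.phi_map, phantom.phi_map, est.mask)
print(f"acquisitions:        {stack.n_acquisitions}")
print(f"estimated pixels:    {int(est.mask.sum())} of {int(phantom.tissue_mask.sum())} tissue pixels")
print(f"circular mean phi:   {summary.circular_mean:.2f} deg (truth 30.00)")
print(f"circular std:        {summary.circular_std:.2f} deg")
print(f"orientation RMSE:    {rmse:.2f} deg")
```

which prints

```
acquisitions:        109
estimated pixels:    404 of 1024 tissue pixels
circular mean phi:   30.01 deg (truth 30.00)
circular std:        2.44 deg
orientation RMSE:    2.44 deg
```

The unestimated tissue pixels are those masked by the Rose criterion: around
the α = β cancellation depth (here ≈ 2 mm, the inverse attenuation) and
below it, the modulation amplitude falls under five background standard
deviations; `phi_interp` carries the circular linear interpolation across
those areas. The raw harmonic phase flips by 90° at that depth; the
recovered ϕ map does not — that correction is the point of the estimator.

The same pipeline is available from the shell:

```bash
dspa simulate --config config.yaml --out run.h5
dspa analyze  --in run.h5
dspa recover  --config config.yaml --in run.h5
dspa report   --config config.yaml --in run.h5 --out report/
```

with a YAML config holding `phantom` (preset or explicit layers + grid),
`sweep`, `noise`, `fit` and `report` blocks; every stage writes a manifest
(config, seed, versions) next to its output.

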