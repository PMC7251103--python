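# sawdesign

Design the boundary of a microfluidic channel so that the acoustic pressure
field inside it takes a shape you choose.

When a travelling surface acoustic wave (SAW) runs under a water-filled
channel whose walls have a lower sound speed than the fluid (e.g. PDMS),
total internal reflection limits the acoustic sources to the substrate
directly beneath the fluid. The resulting diffraction produces lines of
time-averaged pressure minima parallel to the channel walls — the places
where suspended cells and microparticles collect. Because the pattern is set
entirely by the channel outline, the *geometry is the design knob*: no
transducer changes are needed. The forward problem (boundary → field) is a
fast Huygens–Fresnel superposition; the inverse problem (desired field →
boundary) is what this package solves, with a neural network trained on
synthetic simulated data.

The package provides, for microfluidics and acoustofluidics researchers:

* `sawdesign.acoustics` — forward field simulator: the channel acts as a
  distributed source with boundary condition
  `ω ξ₀ e^{−α x_d} e^{−ikx}`, convolved with the spherical wave function
  `(R+1)^{−1} e^{−iωR/c_f}`; time-averaged amplitude `0.5·|P|`. Includes the
  analytic wall-fringe spacing
  `λ_θ = λ_l sin θ / sin(θ − asin((c_f/c_s) sin θ))`.
* `sawdesign.shapes` — star-shaped boundaries as truncated Fourier series of
  the radius, `r(θ) = A0/2 + Σ Aₙ cos nθ + Bₙ sin nθ` (N = 20, 41
  coefficients), plus the randomized perturbed-polygon generator.
* `sawdesign.dataset` — synthetic training corpora: binarized 151×151
  design-region fields (22,801-vectors) paired with the generating
  coefficients, with seeded 80/10/10 splits and HDF5 storage.
* `sawdesign.inverse_net` — a 4-hidden-layer ReLU regression network
  (Adam, RMSE-tracked, z-scored targets) mapping field images to the 41
  coefficients.
* `sawdesign.design` — end-to-end design and the 4-step self-consistency
  loop (simulate → invert → re-simulate → compare), with autocorrelation and
  field energy-residual metrics and a target-coverage score.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
import numpy as np
from sawdesign import (SimConfig, compute_pressure, design_region,
                       pattern_spacing, fit_fourier, polygon_radius)

cfg = SimConfig()  # 300x300 px at 2 um, 40 um SAW on LiNbO3 under water
R = 1.275 * cfg.design_half_diagonal / np.cos(np.pi / 6)
hexagon = fit_fourier(lambda t: polygon_radius(6, R, 0.0, t), n_coeffs=20)
field = compute_pressure(hexagon, cfg)
region = design_region(field)
lam = pattern_spacing(np.pi / 2, cfg.fluid_wavelength,
                      cfg.fluid_sound_speed, cfg.substrate_sound_speed)
print(f"drive frequency:       {cfg.frequency/1e6:.2f} MHz")
print(f"fluid wavelength:      {cfg.fluid_wavelength*1e6:.2f} um")
print(f"wall-parallel spacing: {lam*1e6:.2f} um")
print(f"design-region peak |P|: {region.max():.4g} (a.u.)")
```

prints

```
drive frequency:       99.75 MHz
fluid wavelength:      14.94 um
wall-parallel spacing: 16.10 um
design-region peak |P|: 1.579e+09 (a.u.)
```

A 40 µm SAW at ≈100 MHz gives a 14.94 µm wavelength in water; next to a
channel wall parallel to the propagation direction the pressure-minima
lines repeat every 16.10 µm (the `θ = π/2` value of the spacing law — the
refraction correction stretches the fluid wavelength by ≈8%). The peak
amplitude is in arbitrary units proportional to the substrate displacement
`ξ₀`.

The full inverse loop from the shell:

```bash
sawdesign gen-dataset --n 20000 --seed 7 --out train.h5
sawdesign train --data train.h5 --epochs 250 --seed 7 --out model.ckpt
sawdesign predict --model model.ckpt --mask target.png --out shape.csv
sawdesign design  --model model.ckpt --mask target.png --out result_dir/
sawdesign verify  --model model.ckpt --shape shape.csv
sawdesign simulate --coeffs shape.csv --out field.h5 --png field.png
```

`design` writes `shape.csv` (boundary coefficients), `field.h5` /
`field.png` (the re-simulated field) and `metrics.json` (flat name→number
map with `target_coverage`, the fraction of requested pattern pixels within
2 px of a realized binarized maximum).

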