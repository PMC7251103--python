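# Methods

## Physical model

A travelling surface acoustic wave (SAW) on a piezoelectric substrate
couples into the fluid of a microchannel bonded above it. Where the channel
wall (a material with lower sound speed than the fluid, e.g. PDMS) covers
the substrate, total internal reflection prevents the substrate motion from
radiating into the channel; only substrate directly under fluid acts as a
source. Each source pixel radiates a spherical wavelet, and the time-averaged
pressure amplitude in the channel plane is the magnitude of their
superposition (Huygens–Fresnel construction):

* Source strength at a fluid pixel:
  `BC(x) = ω ξ₀ exp(−α x_d) exp(−i k x)`, with `ω = 2πf` the drive angular
  frequency, `ξ₀` the substrate displacement amplitude, `k = 2π/λ_SAW`,
  `x` the global coordinate along the propagation direction and `x_d` the
  distance from the row's leading fluid edge. The phase factor uses the
  global coordinate because the SAW phase accumulates continuously along the
  substrate; the attenuation distance starts at the channel edge because the
  wave is damped by fluid loading only where fluid sits on the substrate.
* Spherical wave function: `SWF(R) = (R + 1)⁻¹ exp(−i ω R / c_f)`,
  normalized to unity at the substrate/liquid interface (`R = 0`). The
  `+1` in the amplitude rolloff is expressed in grid pixels by default
  (`rolloff_unit: pixel`), making the near-field normalization
  grid-consistent; the phase always uses physical length. A `physical`
  option expresses the rolloff in metres instead.
* Complex field: discrete 2-D convolution `P = SWF ∗ BC`, evaluated exactly
  (FFT-based circular convolution at a padded size that reproduces the
  linear convolution at every grid pixel); time-averaged amplitude
  `0.5·|P|`, zeroed outside the fluid mask.

Velocity contributions to the radiation potential, channel-wall reflections
(≈4% at a PDMS/water interface), acoustic streaming and 3-D/channel-height
effects are outside the model, as are non-star-shaped channels (the radius
parameterization below cannot represent them).

The analytic anchor is the diffraction spacing of the pressure-minima lines
that form parallel to a flat wall:

`λ_θ = λ_l sin θ / sin(θ − asin((c_f/c_s) sin θ))`

where `λ_l = c_f/f` is the fluid wavelength and `θ` is measured between the
SAW propagation direction and the wall normal. The convention matters: a
wall parallel to the propagation direction is `θ = π/2` (spacing
`λ_l/√(1 − (c_f/c_s)²)` perpendicular to the wall), while the spacing along
the propagation direction behind a perpendicular leading wall is the
`θ → 0` limit `λ_l/(1 − c_f/c_s)`. Both limits, and the intermediate
angles 30°–60°, are verified against the simulator in the test suite: a
stationary-phase argument shows the simulated fringe wavenumber along the
wall normal is `√(k_l² − k² cos²ψ) − k sin ψ` for a wall at angle `ψ` to
the propagation direction, which is algebraically identical to `2π/λ_θ`
with `θ = π/2 − ψ`. This identity holds only with the globally continuous
SAW phase above; re-zeroing the phase at each row's channel edge destroys
it, which fixed the phase convention.

### Default parameters

| parameter | default | meaning |
| --- | --- | --- |
| grid | 300 × 300 px, 2 µm/px | 600 × 600 µm simulated domain |
| design region | 151 × 151 px (302 µm), centered | window the inverse problem is posed on |
| λ_SAW | 40 µm | IDT pitch wavelength |
| c_f | 1490 m/s | water |
| c_s | 3990 m/s | SAW speed on 128° Y-X LiNbO₃, giving f = c_s/λ_SAW ≈ 99.75 MHz |
| ξ₀ | 1 (a.u.) | amplitudes are linear in it |
| α | ρ_f c_f / (ρ_s c_s λ_SAW) ≈ 2.0 × 10³ m⁻¹ | fluid-loading attenuation (ρ_f = 1000, ρ_s = 4650 kg/m³) |

All overridable via `SimConfig`.

## Shape representation

A channel boundary is `r(θ) = A0/2 + Σₙ Aₙ cos nθ + Bₙ sin nθ` truncated at
N = 20 (41 parameters). Fourier analysis uses the rectangle rule on a
uniform θ grid (M = 2048 by default; exactly the DFT, spectrally accurate
for smooth radius functions and O(1/M²) at polygon corner kinks — tests that
assert machine-precision sparsity use finer grids). Shapes are centered on
the design-region center; a pixel is fluid iff its center lies strictly
inside the boundary, tested by the exact radius comparison
`|p − c| < r(θ_p)`, which for star-shaped boundaries equals the even-odd
polyline rule without polyline discretization error.

## Synthetic training corpus

Each sample draws a regular polygon with 3–8 sides (uniform side count),
inradius uniform in 1.1–1.45 × the design region's half-diagonal (so the
channel always encloses the design window, with some margin for the
perturbation), and uniform rotation; fits N = 20 coefficients; multiplies
each of the 41 coefficients by an independent factor uniform in
[0.75, 1.25]; and rejection-resamples until the perturbed boundary still
encloses the design region. The field is simulated, the design region
cropped, binarized at 75% of its maximum (ties at the maximum are kept, so
the input is never empty), and flattened row-major into a 22,801-vector.
Targets are the generating coefficients ordered `[A0, A1..A20, B1..B20]`.
Splits are 80/10/10 by a seeded permutation; inputs are stored as bytes in
HDF5 and everything regenerates bit-identically from the stored provenance
(seed, config, perturbation settings).

Training inputs and design-time inputs use the same 75%-binarized format:
`predict_shape` auto-binarizes amplitude rasters at the same threshold, so
the distribution the network sees at inference matches what it was trained
on.

What the generator does *not* emulate: fabrication tolerances, wall
compliance, measurement noise, or shapes outside the perturbed-polygon
family — passing tests say the inverse solver works on this family under
the forward model, not that it transfers to arbitrary hand-drawn channels
or to experimental devices.

## Inverse network

A fully connected feedforward regressor with 4 ReLU hidden layers and a
linear 41-wide output, trained with Adam against mean-squared error on
z-scored coefficients (normalizer fitted on the training split and stored
with the model; without it A0, of order 10⁻⁴ m, dominates the loss over
the 10⁻⁶-order high harmonics). Inputs are the {0,1} vectors cast to
float32 with the training-set per-pixel mean subtracted (zero-centering the
sparse binary features; the mean is stored in the checkpoint). Default
architecture tapers 2048-1024-512-128; training history records train/val
RMSE per epoch; early stopping is off by default (a fixed epoch budget)
with an optional patience setting. Checkpoints bundle weights, normalizer,
pixel mean and the generating `SimConfig`, so design runs are
self-contained.

The test suite trains a reduced configuration sized for a single CPU:
12,500 samples (10,000 train / 1,250 val / 1,250 test), hidden widths
256-128-64-32, batch 256, learning rate 10⁻³, 45 epochs. These sizes are
the package's scaled study conditions; the reference configuration in the
literature of this device class is an order of magnitude larger
(20,000 samples, GPU, 250 epochs).

### What the scaled-down inverse solver does and does not achieve

With the reduced corpus the trained network closes the
simulate→invert→re-simulate loop with field residuals a factor ~2 below an
untrained (randomly initialized) network of the same architecture, and its
coefficient errors on held-out shapes beat nearest-neighbor and kernel-ridge
baselines on the dominant harmonics. It does **not** reach a 10%-of-σ
median error on every coefficient at this scale: the constant term A0
(absolute channel size) floors at ≈0.2–0.4 σ for every model class we
probed (MLP, 1-nearest-neighbor ≈ 0.31, kernel ridge ≈ 0.21, constant mean
0.79), indicating the binarized 75%-threshold design-region pattern
under-determines absolute size at ~10⁴ training samples. See the test
suite's recovery test for the exact assertion.

## Residual metrics

Both verification metrics are relative *energy* ratios:
`field_residual = Σ(â − b̂)² / Σ â²` on peak-normalized amplitudes, and
`autocorr_residual` the same ratio on unit-peak 2-D autocorrelations of
mean-subtracted amplitudes (pattern structure, position-blind). The energy
convention is chosen because it reproduces the characteristic magnitudes
this device literature reports for N = 20 and N ≳ 80 series approximations
(10⁻²–10⁻³, and <1% autocorrelation residual); the plain L2-norm ratio is
available via `squared=False`. Both are normalized by the first argument
(asymmetry below ~10% on comparable fields) and are zero on identical
inputs; constant and all-zero rasters are rejected.

`target_coverage` scores a design: the fraction of target-mask pixels lying
within d = 2 px (dilation by a Euclidean disk) of a binarized-maxima pixel
of the realized design-region field. Target masks are interpreted as
"pattern regions": time-averaged maxima and minima alternate at λ_θ/2, so a
mask marks where the tightly-spaced extrema pair (and hence particle
aggregation lines) should sit, not one polarity exclusively.

## Numerical choices and degenerate inputs

* Binarization threshold is strict `>` with ties at the exact maximum kept,
  so a constant raster binarizes to all-true and the vectorized input is
  never empty; all-zero rasters raise.
* `pattern_spacing` returns `+inf` when the refracted-angle argument
  degenerates (equal sound speeds) and raises when `(c_f/c_s)·sin θ > 1`.
* Fourier fitting requires M ≥ 4N + 2 samples and strictly positive radii;
  boundary export raises on non-positive reconstructed radii, while network
  predictions that violate positivity are returned with a warning (the
  caller may still inspect or project them).
* The FFT convolution is validated against an O(n⁴) direct superposition
  oracle to ≤10⁻¹⁰ relative error on small grids.
* Determinism: dataset generation, training and design are reproducible
  bit-for-bit (or to ≤10⁻⁶ in final RMSE for training) from their seeds on
  a fixed BLAS configuration.

## Known limitations

* The radius series cannot represent non-star-shaped (multi-valued radius)
  channels.
* Printed third-party coefficient examples for a rotated triangle cannot be
  reproduced numerically because the source shape's scale is not stated;
  tests assert the symmetry-dominance pattern instead.
* The inverse solver's absolute-size recovery is sample-limited at desk
  scale (see above).
* Fields are 2-D in-plane; device-height resonances and streaming are out
  of scope.
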