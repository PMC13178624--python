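# Methods

`sawoce` estimates the depth-resolved phase velocity of a surface acoustic
wave (SAW) from 3-D complex optical-coherence-elastography (OCE) volumes, and
locates stiffness interfaces between tissue layers.  Two estimators share one
preprocessing path: a physics-based spectral estimator (the package's
reference method) and a learned inverter (PVNet).  This note records the
models, the defaults and why they are what they are, and what the synthetic
data can and cannot establish.

## Observable and preprocessing

The raw observable is a complex OCT field `c[z, x, t]` (axial depth × lateral
position × time) with spacings `dz` (µm), `dx` (µm), `dt` (s).  A shaker
drives a SAW at `f0` (default 4 kHz) that propagates along `+x`; axial tissue
motion modulates the optical phase.

Wave motion is extracted as lag-1 phase differences via the conjugate product
`arg(c[z,x,t+1] · c̄[z,x,t])` (Kasai-style), which is wrap-safe and identical
modulo 2π to subtracting frame phases.  No unwrapping is applied by default:
the default modulation depth keeps |Δφ| < π.  A 1-D temporal unwrap flag
exists for stress tests.

Depth must be measured from the sample surface, so the surface is detected
per lateral position by thresholding the time-averaged magnitude at
`noise_mean + 5·noise_std`.  The noise floor is estimated from the dimmest 5 %
of depth rows — above-surface rows in a raw volume, vacated zero rows in a
flattened one — which makes detection idempotent: re-running it on a flattened
volume returns zeros.  The result is median-filtered (window 11) and each
A-line is shifted by an integer number of pixels (no sub-pixel interpolation,
preserving the complex statistics the spectral estimator consumes).

## Spectral estimator (f–k centroid)

For each retained depth layer the lateral×temporal phase-difference image is
mean-removed, apodized with a separable symmetric Hann window, and 2-D
Fourier-transformed with zero padding (next power of two of twice the size;
padding reduces centroid quantization).  Magnitude spectra from ±2 neighbour
layers (truncated at the stack edges so the profile keeps one estimate per
depth) are averaged into a stabilized energy map `S(k, f)`; `k` is in cycles
per metre throughout, so the phase velocity is simply `c = f_c / k_c` with no
2π factor, where

    f_c = Σ f·S / Σ S,    k_c = Σ k·S / Σ S

are the energy-weighted centroids over a region of interest (ROI).

* **ROI.**  Derived from the excitation frequency and a velocity search band:
  `f ∈ f0·(1 ± 0.5)` and `k ∈ [f_min/c_max, f_max/c_min]` with
  `c ∈ [1, 20]` m/s — wide enough to bracket every soft-tissue SAW velocity
  of interest (≈2–8 m/s) with margin.
* **Central-energy mask.**  Only bins at or above 25 % of the ROI maximum
  enter the centroid.  The mask matters: broadband noise spread over the wide
  ROI otherwise drags `k_c` toward the ROI middle (−23 % velocity bias at
  noise level 0.2 in our benchmarks; ≈1 % with the mask).  The unmasked
  centroid remains available (`central_threshold=0`) and is what the
  brute-force oracle in the tests checks.
* **Quadrant selection.**  The FFT of a real phase image is conjugate
  symmetric; the `f ≥ 0` half-plane is kept and, of the two wavenumber signs,
  the one carrying more ROI energy — a travelling wave concentrates in one
  half, and energy voting needs no prior on the propagation direction.
* **Input choice.**  The transform operates on phase-difference slices by
  default; a config switch (`use_complex_field`) feeds the complex M-scan
  slices instead.  Both recover the same homogeneous-phantom velocity in the
  tests; the phase-difference path is the default because its spectrum is
  single-lobed at the excitation frequency.

Depths whose spectrum is degenerate (no ROI energy) are recorded as missing;
a profile with more than 50 % missing depths is rejected.

## Profile smoothing and interface detection

Raw profiles are smoothed with robust LOESS: local linear fits over the 30
nearest samples with tricube distance weights, robustified by 5 bisquare
reweighting passes on residuals scaled by 6×median absolute residual.  The
30-sample default matches a 100-depth profile; for shorter profiles the
window should be scaled proportionally (the pipeline exposes it).  Local
linear fitting reproduces straight lines exactly, so smoothing cannot create
a spurious velocity gradient.

The layer boundary is the breakpoint of a bilinear fit: two *independent*
ordinary-least-squares lines (a discontinuity — the velocity jump — is
allowed at the interface), with the breakpoint found by exhaustive search
over all splits leaving at least `min_segment = 5` points per side (5 keeps
per-segment OLS well posed; the choice is ours).  Ties go to the smallest
breakpoint index.  By construction the two-segment SSE never exceeds the
single-line SSE.  The fit is performed on the smoothed profile by default
(`use_raw` switches to the raw one); both modes exist because either reading
of the estimation order is defensible.

Real samples may be homogeneous, so a "no interface" verdict is issued when
the fitted jump is below 0.3 m/s or the single-line SSE is less than 1.05×
the bilinear SSE — a principled null rather than always reporting a
breakpoint.

Depth indices convert to physical depth as `z · dz / 1000` mm; at the default
`dz = 4.7` µm, index 35 is 0.165 mm and index 15 is 0.071 mm (3-decimal
rounding).

## Synthetic volumes

No public SAW-OCE volumes exist, so the simulator is a first-class module and
the source of all test and training data.  The forward model is

    c[z, x, t] = A(z, x) · exp(i·φ(z, x, t)) + n
    φ = a · sin(2π f0 (t·dt − x·dx / c(z')))

with `z'` the depth below the local surface, `c(·)` piecewise constant per
layer, amplitude decaying exponentially below the surface (e-folding one
volume depth) and mildly along `x`, zero signal above the surface, and `n`
i.i.d. circular complex Gaussian noise (std relative to unit surface
amplitude).  Defaults: modulation depth 1 rad (keeps lag-1 differences inside
±π), noise 0.05, excitation 4 kHz.

Deliberate simplifications, and hence what passing tests do *not* show about
real tissue: the excitation is the sinusoidal fundamental of the square-wave
drive (optional harmonics exist but the spectral ROI is centred on the
fundamental); velocity enters only through the local layer — no guided-wave
mode coupling, dispersion or viscoelasticity; no OCT speckle statistics or
decorrelation; surface topography is limited to flat/tilt/sinusoid.  Tests on
this generator establish correctness of the estimators under their own model
assumptions, not robustness to mode conversion or speckle noise.

Two geometry presets exist.  The full preset mirrors the acquisition:
384×600×600 voxels, dz 4.7 µm, dx 8.6 µm, ≥8 excitation cycles per
acquisition.  The fast preset (64×128×128) used throughout the tests coarsens
the lateral sampling to 40 µm so that its 128 columns preserve the ~5.1 mm
aperture: wavenumber *resolution* (1/aperture), not sampling density, bounds
f–k estimation, and a 1.1 mm aperture would hold less than one wavelength at
5 m/s.  40 µm sampling still oversamples the slowest waves of interest by a
factor of ~3 relative to spatial Nyquist.

## PVNet

PVNet regresses the phase velocity at one depth directly from that depth's
lateral×temporal phase image.  Images are wrapped to [−π, π), scaled by 1/π,
and bilinearly resized to the network input (the resize lives outside
`forward`, which rejects wrong sizes rather than silently rescaling).

Architecture: a 4×4/stride-4 patch-embedding stem, then four stages at
halving spatial resolution.  Each stage is `depth` ConvEncoder blocks —
`x + Conv1×1(GELU(Conv1×1(BN(DWConv3×3(x)))))` — followed by one SwiftFormer
block: local mixing (DWConv3×3 + Conv1×1), flattening to tokens, efficient
additive attention with rotary position embeddings on the learned Q/K
projections, and a linear block (DWConv3×3 + BN + Conv1×1).  Additive
attention forms a single global query from a softmax saliency over tokens
(`α = softmax(Q·w_a/√D)`, `q = Σ αᵢQᵢ`) and modulates the keys with it
(`Linear(K ⊙ q) + Q`), which is linear rather than quadratic in token count.
RoPE rotates adjacent feature pairs by `m·base^(−2i/D)` for (row-major
flattened) token position `m`, so Q–K interactions depend only on relative
position; the scaling of the saliency logits is `1/√D`.  Global average
pooling and a two-layer head produce one velocity in m/s.

The original network's exact stage dimensions are not public; this package
defines its own presets.  The `tiny` preset (dims 16/32/48/64, one
ConvEncoder per stage, 64×64 input, expansion 2; ~125 k parameters) is the
desk-scale working model — a single forward pass is ~10 ms on one CPU core —
while `S`/`base`/`L` scale the same blocks up to the 320×320 input of the
full-scale design.  Parameter counts deliberately do not match the original
multi-hundred-million-parameter models.

The tensor backend is a compact numpy reverse-mode autodiff engine written
for this package (convolutions lowered to BLAS matmuls via im2col, depthwise
kernels as nine shifted multiply-adds, hand-written backward rules verified
against central differences).  It runs float32 by default; the gradient
tests switch it to float64.

**Training protocol.**  MSE loss, Adam, batch 128, early stopping on
validation loss with patience 15, fully seeded (split, init, and shuffle
seeds all derive from one training seed).  The protocol-default learning
rate is 1e-4, matching standard practice for this task at full scale; the
desk-scale benchmark uses 1e-3 because the tiny model on small synthetic sets
is far from the instability regime and converges several times faster.  On
tiny datasets (hundreds of images) a smaller batch (32) is preferable — at
batch 128 an epoch is a single update.  An optional `target_val_mae` stop
ends a study once validation MAE is comfortably below the level under test
(the benchmark uses 0.2 m/s against a 0.3 m/s acceptance level), which keeps
run times down without changing what is being demonstrated.

**Desk-scale benchmark.**  2,000 phase images from 40 homogeneous phantoms
with velocities uniform in [2, 8] m/s at noise 0.1, 80/20 train/validation
split, tiny preset: held-out MAE reaches < 0.3 m/s within 30 epochs (typical
runs reach ≈0.15–0.25 m/s in 10–25 epochs, ~2–3 minutes per seed on one CPU
core).  This is a scaled-down analogue of the full-scale regime (reported
MAEs there are ≈0.12–0.16 m/s on real data), not a reproduction of it.

Labels for synthetic training are the simulator's true velocities; the
pipeline's DLI stage can instead follow the measurement protocol in which
the rLOESS-smoothed spectral estimates serve as ground truth (`labels: nsa`).

## Numerical choices and degenerate inputs

* FFT sizes are powers of two; physical axes come from `fftfreq` with the
  true spacings, `k` in cycles/m via `dx·1e-6`.
* Simulation configs are validated against both temporal (`f0 < 1/(2dt)`)
  and spatial (`f0/c_min < 1/(2dx)`) Nyquist limits at construction.
* Zero-thickness layers are legal and equivalent to omitting the layer; the
  last layer extends to the bottom of the volume.
* `centroid_velocity` raises on zero ROI energy and on a vanishing
  wavenumber centroid instead of returning infinities.
* rLOESS stops its robust iterations when the median absolute residual is
  zero (exact fit) — the bisquare weights are undefined there and the fit
  cannot improve.
* In the exact-tie case the bilinear search returns the smallest breakpoint;
  SSE comparisons in tests use 1e-9 absolute slack for float accumulation.

## Problem sizes in tests and the acceptance script

All quantitative checks run on the 64×128×128 preset (40-depth profiles),
20-profile breakpoint ensembles, 100 random centroid maps, and the
2,000-image training benchmark with 3 seeds — sizes chosen so the whole suite
runs in minutes on a single core while every claim is still measured, not
assumed.

## Known limitations

* The spectral estimator's accuracy degrades when the lateral aperture holds
  less than ~1 wavelength; the simulator presets are sized to avoid this, but
  the estimator itself does not warn about it.
* The ±2-layer spectral averaging and the robust smoother blur step
  interfaces over ~5 depth indices; the fitted velocity jump underestimates a
  true step even when the breakpoint is localized correctly.
* Thin superficial layers (thickness ≲ the averaging window) merge into the
  layer below, mirroring the physical resolution limit of depth-averaged
  spectra.
* The "no interface" thresholds (0.3 m/s jump, 1.05 SSE ratio) are pragmatic
  defaults validated on the simulator, not universal constants.
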