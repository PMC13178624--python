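# sawoce

Depth-resolved surface-acoustic-wave (SAW) phase-velocity estimation for
optical coherence elastography (OCE).

Tissue stiffness varies with depth — skin layers, sub-surface lesions,
layered phantoms — and the phase velocity of a surface acoustic wave tracked
by OCT is a direct mechanical probe of it.  `sawoce` turns a 3-D complex OCE
volume `c[z, x, t]` (depth × lateral × time) carrying a 4 kHz SAW into a
depth-resolved velocity profile `v(z)` and the location of the layer
interface, two ways:

* **Spectral estimator (NSA).**  Per depth layer, the lateral–temporal
  phase-difference image is Hann-apodized and 2-D Fourier transformed;
  magnitude spectra from ±2 neighbouring layers are averaged into an energy
  map S(k, f), and the velocity is the ratio of energy-weighted centroids

      v(z) = f_c / k_c,   f_c = Σ f·S / Σ S,   k_c = Σ k·S / Σ S

  over a region of interest around the excitation frequency (k in cycles/m,
  so no 2π).  Profiles are smoothed with robust LOESS (tricube weights,
  bisquare reweighting) and the layer boundary is the breakpoint of a
  two-segment linear fit v(z) = a₁z+b₁ (z < z_break), a₂z+b₂ (z ≥ z_break)
  minimizing total SSE, with a velocity jump allowed at the interface.

* **Learned inverter (PVNet).**  A hybrid CNN/transformer that regresses the
  velocity at one depth directly from that depth's phase image: four
  hierarchical stages of ConvEncoder blocks plus SwiftFormer blocks whose
  token mixing is *efficient additive attention* (a softmax-pooled global
  query, linear in token count) with rotary positional embeddings on Q/K.
  It runs on a self-contained numpy autodiff engine and trains with
  Adam + MSE + early stopping, on CPU.

Because no public SAW-OCE datasets exist, the package ships a first-class
simulator that renders complex volumes with known piecewise-constant
velocity-vs-depth, surface tilt/topography, depth decay and complex noise —
the source of all test and training data, and the ground truth every claim
is measured against.  Intended users: OCE/elastography researchers who want
a transparent, fully seeded reference implementation of f–k centroid
velocimetry and attention-based velocity inversion at desk scale.

## Worked example

```python
import numpy as np
from sawoce import (small_config, simulate_volume, detect_surface,
                    flatten_volume, extract_phase_stack, nsa_profile,
                    rloess_smooth, detect_interface)

# stiff-on-soft phantom: 5.5 m/s over 3.1 m/s, interface 20 layers deep
cfg = small_config(layers=((20, 5.5), (44, 3.1)), noise_sigma=0.05, seed=2)
vol = simulate_volume(cfg)

flat = flatten_volume(vol, detect_surface(vol))
profile = rloess_smooth(nsa_profile(extract_phase_stack(flat, n_depths=40)),
                        window=11)
verdict = detect_interface(profile)
print(verdict.fit.z_break, f"{verdict.depth_mm:.3f} mm", f"{verdict.fit.jump:.2f} m/s")
```

Output (examples/layered_interface.py prints the annotated version):

```
interface detected: True
breakpoint at depth index 19 (true interface at 20), 0.089 mm below the surface
velocity jump at the interface: 2.06 m/s (true step 2.4 m/s)
segment slopes: -0.001 / -0.022 m/s per index
```

The breakpoint lands within one depth index of the true interface; the
fitted jump underestimates the true 2.4 m/s step because the ±2-layer
spectral averaging and the smoother blur the transition (see
docs/methods.md).  On a homogeneous 3.2 m/s phantom the same pipeline
returns a depth-mean of 3.19 m/s and a "no interface" verdict
(examples/homogeneous_phantom.py).

More examples: `examples/train_pvnet.py` trains the tiny PVNet variant on
simulated phase images and reports held-out MAE in m/s.

## Command line

Every stage is also a subcommand communicating through documented formats
(HDF5 volumes, CSV profiles, JSON fits):

```bash
sawoce run -c pipeline.yaml -o out/     # simulate → flatten → NSA → interface
sawoce simulate | preprocess | nsa | interface | train | predict
```

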