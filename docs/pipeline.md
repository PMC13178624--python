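# Pipeline configuration (YAML)

`sawoce run -c pipeline.yaml -o outdir` executes
simulate/load → surface flattening → spectral estimation → smoothing +
interface detection, optionally followed by the deep-learning inversion
stage.  All keys except one of `simulate`/`volume` are optional.

```yaml
seed: 1                      # master seed; every stochastic stage derives from it

simulate:                    # EITHER: render a synthetic volume ...
  preset: small              # small = 64x128x128 test preset, full = 384x600x600
  layers: [[20, 5.5], [44, 3.1]]   # (thickness in depth indices, velocity m/s)
  noise_sigma: 0.05          # complex noise std relative to unit amplitude
  displacement_amp: 1.0      # peak phase modulation, radians
  surface: {kind: tilt, z0: 8, z1: 16}   # flat | tilt | sine
  f0: 4000.0                 # excitation frequency, Hz
  # any other SimulationConfig field may be overridden here

volume: path/to/volume.h5    # ... OR: load a measured/stored volume

n_depths: 40                 # depth layers retained below the surface

nsa:                         # NSAConfig fields
  depth_radius: 2            # +/- layers averaged per spectrum
  pad_factor: 2
  c_min: 1.0                 # velocity search band for the automatic ROI
  c_max: 20.0
  band: 0.5                  # relative frequency half-width around f0
  centroid_threshold: 0.25   # central-energy mask level

interface:
  window: 11                 # rLOESS window in samples (~30% of the profile)
  min_segment: 5
  jump_threshold: 0.3        # m/s below which "no interface" is reported
  sse_ratio_threshold: 1.05

pvnet:                       # optional DLI stage
  enabled: true
  variant: tiny              # tiny | S | base | L
  labels: nsa                # nsa = smoothed spectral profile as ground truth,
                             # true = simulator velocities (synthetic runs only)
  lr: 1.0e-3
  batch_size: 32
  max_epochs: 20
  patience: 10
```

Artifacts written to the output directory: `volume.h5` (when simulating),
`surface.csv`, `profile.csv` (+ `profile.fit.json`), `summary.txt`,
`manifest.json` (config, seeds, versions), and with the DLI stage
`pvnet_profile.csv` + `pvnet_history.json`.  Rerunning the same config and
seed reproduces `profile.csv` byte for byte.
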