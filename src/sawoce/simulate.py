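"""Synthetic SAW-OCE volume generator with known depth-dependent phase velocity.

The forward model stands in for a swept-source OCT instrument watching a
surface acoustic wave (SAW) driven by a mechanical shaker.  A complex field

    data[z, x, t] = A(z, x) * exp(i * phi(z, x, t)) + n

carries the wave as a phase modulation

    phi(z, x, t) = displacement_amp * sin(2*pi*f0*(t*dt - x*dx / c(z')))

where ``z'`` is the depth below the local sample surface and ``c`` the
piecewise-constant layer velocity.  The amplitude decays exponentially with
depth below the surface and (mildly) along the propagation direction ``+x``;
voxels above the surface contain noise only.  ``n`` is circularly symmetric
complex Gaussian noise.  The excitation is modelled as the sinusoidal
fundamental of the shaker drive at ``f0`` (harmonics optional), which keeps the
frequency–wavenumber ground truth single-lobed and analytically checkable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .core_io import ComplexOCEVolume, VelocityProfile

__all__ = [
    "SimulationConfig",
    "surface_indices",
    "true_profile",
    "simulate_volume",
    "make_training_set",
    "default_config",
    "small_config",
]

UM = 1e-6  # micrometres in metres


class ConfigurationError(ValueError):
    """A simulation configuration violates a physical or sampling constraint."""


@dataclass
class SimulationConfig:
    """Everything that defines one synthetic acquisition.

    Attributes
    ----------
    shape:
        (Z, X, T) — axial depth, lateral position, time frames.
    dz, dx:
        Pixel spacings, micrometres.
    dt:
        Frame interval, seconds.
    f0:
        Excitation frequency, hertz.
    layers:
        Ordered (thickness_in_depth_indices, phase_velocity_m_per_s) pairs,
        measured downward from the local surface.  Thicknesses may sum to less
        than Z; the last layer is extended to the bottom.
    displacement_amp:
        Peak phase modulation, radians.
    depth_decay, lateral_decay:
        Amplitude e-folding lengths in depth / lateral indices.
    surface:
        Surface description: ``{"kind": "flat", "z0": ...}``,
        ``{"kind": "tilt", "z0": ..., "z1": ...}`` or
        ``{"kind": "sine", "z0": ..., "amp": ..., "periods": ...}``.
    noise_sigma:
        Std of the complex noise relative to unit (surface) signal amplitude;
        each real/imag component has std ``noise_sigma / sqrt(2)``.
    harmonics:
        Optional extra odd harmonics of the square-wave drive, as a list of
        (multiple, relative_amplitude); empty by default.
    seed:
        Seed for the noise generator; same seed, same volume, bit for bit.
    """

    shape: tuple[int, int, int] = (384, 600, 600)
    dz: float = 4.7
    dx: float = 8.6
    dt: float = 1.0 / (4000.0 * 75.0)
    f0: float = 4000.0
    layers: Sequence[tuple[int, float]] = ((384, 4.0),)
    displacement_amp: float = 1.0
    depth_decay: float = 384.0
    lateral_decay: float = 2400.0
    surface: dict[str, Any] = field(default_factory=lambda: {"kind": "flat", "z0": 10})
    noise_sigma: float = 0.05
    harmonics: Sequence[tuple[int, float]] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        Z, X, T = self.shape
        if min(Z, X, T) < 2:
            raise ConfigurationError("every volume axis needs at least 2 samples")
        if self.dz <= 0 or self.dx <= 0 or self.dt <= 0:
            raise ConfigurationError("dz, dx, dt must be positive")
        if self.f0 <= 0:
            raise ConfigurationError("excitation frequency must be positive")
        self.layers = tuple((int(th), float(v)) for th, v in self.layers)
        if not self.layers:
            raise ConfigurationError("at least one layer is required")
        if any(th < 0 for th, _ in self.layers):
            raise ConfigurationError("layer thickness cannot be negative")
        if sum(th for th, _ in self.layers) > Z:
            raise ConfigurationError("layer thicknesses must sum to <= Z")
        if any(v <= 0 for _, v in self.layers):
            raise ConfigurationError("layer velocities must be positive")
        if self.displacement_amp < 0 or self.noise_sigma < 0:
            raise ConfigurationError("amplitudes must be nonnegative")
        # temporal Nyquist
        if self.f0 >= 0.5 / self.dt:
            raise ConfigurationError(
                f"temporal Nyquist violated: f0={self.f0} Hz >= 1/(2 dt)={0.5 / self.dt:.1f} Hz")
        # spatial Nyquist: wavenumber f0/c_min (cycles/m) must stay below 1/(2 dx)
        c_min = min(v for _, v in self.layers)
        if self.f0 / c_min >= 0.5 / (self.dx * UM):
            raise ConfigurationError(
                f"spatial Nyquist violated: f0/c_min={self.f0 / c_min:.1f} cycles/m "
                f">= 1/(2 dx)={0.5 / (self.dx * UM):.1f} cycles/m")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def default_config(**overrides: Any) -> SimulationConfig:
    """The full acquisition-scale preset: 384×600×600, dz 4.7 µm, dx 8.6 µm."""
    return SimulationConfig(**overrides)


def small_config(**overrides: Any) -> SimulationConfig:
    """A 64×128×128 preset for fast tests; T spans 8 excitation cycles.

    The lateral spacing is coarsened to 40 µm so the 128 lateral samples keep
    the instrument's ~5.1 mm aperture: wavenumber resolution, not sampling
    density, is what bounds spectral velocity estimates, and a 1.1 mm aperture
    would hold less than one wavelength at the stiffer velocities of interest.
    """
    kw: dict[str, Any] = dict(
        shape=(64, 128, 128), dz=4.7, dx=40.0, dt=8.0 / (4000.0 * 128),
        layers=((64, 4.0),), depth_decay=64.0, lateral_decay=512.0,
        surface={"kind": "flat", "z0": 8},
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def surface_indices(config: SimulationConfig) -> np.ndarray:
    """Integer surface depth index per lateral position, from ``config.surface``."""
    Z, X, _ = config.shape
    s = config.surface
    kind = s.get("kind", "flat")
    x = np.arange(X, dtype=np.float64)
    if kind == "flat":
        surf = np.full(X, float(s.get("z0", 0)))
    elif kind == "tilt":
        surf = s["z0"] + (s["z1"] - s["z0"]) * x / max(X - 1, 1)
    elif kind == "sine":
        surf = s["z0"] + s["amp"] * np.sin(2 * np.pi * s.get("periods", 1) * x / X)
    else:
        raise ConfigurationError(f"unknown surface kind {kind!r}")
    surf = np.rint(surf).astype(np.int64)
    if surf.min() < 0 or surf.max() >= Z:
        raise ConfigurationError("surface profile leaves the volume")
    return surf


def layer_velocity(config: SimulationConfig, depth_below_surface: np.ndarray) -> np.ndarray:
    """Phase velocity at each depth-below-surface index (piecewise constant)."""
    edges = np.cumsum([th for th, _ in config.layers])
    vels = np.array([v for _, v in config.layers])
    idx = np.searchsorted(edges, depth_below_surface, side="right")
    idx = np.clip(idx, 0, len(vels) - 1)
    return vels[idx]


def true_profile(config: SimulationConfig, n_depths: int | None = None) -> VelocityProfile:
    """Ground-truth velocity per depth layer below the (flattened) surface.

    Depth index 0 is the first layer at the surface; ``v_true[z]`` is the
    velocity of the material layer containing ``z``.
    """
    Z = config.shape[0]
    if n_depths is None:
        n_depths = Z - int(surface_indices(config).max())
    depths = np.arange(n_depths)
    return VelocityProfile(depth_index=depths, dz=config.dz,
                           v_true=layer_velocity(config, depths))


def simulate_volume(config: SimulationConfig) -> ComplexOCEVolume:
    """Render the synthetic complex volume for one configuration.

    Deterministic given ``config.seed``.
    """
    Z, X, T = config.shape
    surf = surface_indices(config)                       # (X,)
    z = np.arange(Z)[:, None]                            # (Z, 1)
    depth_below = z - surf[None, :]                      # (Z, X), <0 above surface
    below = depth_below >= 0

    amp = np.zeros((Z, X))
    amp[below] = np.exp(-depth_below[below] / config.depth_decay)
    amp *= np.exp(-np.arange(X)[None, :] / config.lateral_decay)

    c = layer_velocity(config, np.clip(depth_below, 0, None))   # (Z, X)
    x_m = (np.arange(X) * config.dx * UM)[None, :]              # lateral position, m
    t_s = np.arange(T) * config.dt                              # (T,)

    # travelling-wave argument psi[z,x,t] = 2*pi*f0*(t - x/c(z'))
    delay = x_m / c                                             # (Z, X) seconds
    psi = 2 * np.pi * config.f0 * (t_s[None, None, :] - delay[:, :, None])
    phi = config.displacement_amp * np.sin(psi)
    for mult, rel in config.harmonics:
        phi += config.displacement_amp * rel * np.sin(mult * psi)

    data = (amp[:, :, None] * np.exp(1j * phi)).astype(np.complex128)
    if config.noise_sigma > 0:
        rng = np.random.Generator(np.random.PCG64(config.seed))
        comp_sigma = config.noise_sigma / np.sqrt(2.0)
        data += comp_sigma * (rng.standard_normal(data.shape)
                              + 1j * rng.standard_normal(data.shape))

    meta = {
        "f0": config.f0,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "displacement_amp": config.displacement_amp,
        "noise_sigma": config.noise_sigma,
        "surface": config.surface,
        "layers": [list(l) for l in config.layers],
    }
    return ComplexOCEVolume(data=data, dz=config.dz, dx=config.dx, dt=config.dt, meta=meta)


def make_training_set(
    configs: Sequence[SimulationConfig],
    depths_per_volume: int = 100,
    shuffle_seed: int = 0,
    depth_offset: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build labelled (phase image, true velocity) pairs from simulated volumes.

    For each configuration the volume is simulated, flattened on its detected
    surface, and ``depths_per_volume`` consecutive depth layers starting at
    ``depth_offset`` below the surface are extracted as lateral×temporal
    phase-difference images, each labelled with the layer's true velocity.
    Pairs from all volumes are shuffled together with ``shuffle_seed``.

    Returns
    -------
    images : float64 array (N, X, T-1), phase differences in [-pi, pi)
    labels : float64 array (N,), phase velocity in m/s
    """
    from .preprocess import detect_surface, extract_phase_stack, flatten_volume

    images: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for config in configs:
        usable = config.shape[0] - int(surface_indices(config).max()) - depth_offset
        if depths_per_volume > usable:
            raise ValueError(
                f"depths_per_volume={depths_per_volume} exceeds usable depth range {usable}")
        vol = simulate_volume(config)
        surf = detect_surface(vol)
        flat = flatten_volume(vol, surf)
        stack = extract_phase_stack(flat, depths_per_volume, depth_offset=depth_offset)
        images.append(stack.phase)
        labels.append(layer_velocity(config, stack.depth_indices()))
    X = np.concatenate(images, axis=0)
    y = np.concatenate(labels, axis=0)
    order = np.random.Generator(np.random.PCG64(shuffle_seed)).permutation(len(y))
    return X[order], y[order]
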