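"""Surface detection, volume flattening, and lag-1 phase-difference extraction.

The SAW travels along the sample surface, so depth-wise analysis only makes
sense relative to that surface: the surface is located per lateral position
from the time-averaged backscatter magnitude, every A-line is shifted so the
surface sits at depth 0, and phase-difference images are then pulled from
consecutive depth layers.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import medfilt

from .core_io import ComplexOCEVolume, PhaseStack

__all__ = ["detect_surface", "flatten_volume", "extract_phase_stack", "SurfaceError"]


class SurfaceError(RuntimeError):
    """Surface detection failed for one or more lateral positions."""


def detect_surface(vol: ComplexOCEVolume, k_sigma: float = 5.0,
                   noise_rows_frac: float = 0.05, median_window: int = 11) -> np.ndarray:
    """Find the sample surface depth index for every lateral position.

    The time-averaged magnitude image M[z, x] is thresholded at
    ``noise_mean + k_sigma * noise_std``, with the noise floor estimated from
    the dimmest ``noise_rows_frac`` of depth rows — above-surface rows in a raw
    volume, vacated zero-filled rows in an already-flattened one — so detection
    also works when the surface sits at depth 0.  The first super-threshold
    depth per column is taken and the result is median-filtered to reject
    speckle outliers.

    Raises
    ------
    SurfaceError
        If some column never crosses the threshold (lists the columns).
    """
    M = np.abs(vol.data).mean(axis=2)          # (Z, X)
    Z, X = M.shape
    n_noise = max(1, int(round(noise_rows_frac * Z)))
    dimmest = np.argsort(M.mean(axis=1))[:n_noise]
    floor = M[dimmest, :]
    thresh = floor.mean() + k_sigma * floor.std()

    above = M > thresh
    has_surface = above.any(axis=0)
    if not has_surface.all():
        bad = np.flatnonzero(~has_surface)
        raise SurfaceError(
            f"no super-threshold voxel in {bad.size} column(s): {bad[:20].tolist()}"
            + ("..." if bad.size > 20 else ""))
    surface = above.argmax(axis=0).astype(np.int64)

    w = min(median_window, X)
    if w % 2 == 0:
        w -= 1
    if w >= 3:
        surface = medfilt(surface.astype(np.float64), kernel_size=w).astype(np.int64)
    return surface


def flatten_volume(vol: ComplexOCEVolume, surface: np.ndarray) -> ComplexOCEVolume:
    """Shift each lateral column axially so the surface sits at depth 0.

    Integer shifts only — no sub-pixel interpolation — so the complex speckle
    statistics the spectral estimator consumes are untouched.  Rows vacated at
    the bottom are zero-filled; the applied shifts are recorded in ``meta``.
    """
    surface = np.asarray(surface, dtype=np.int64)
    Z, X, T = vol.shape
    if surface.shape != (X,):
        raise ValueError(f"surface must have shape ({X},)")
    if surface.min() < 0 or surface.max() >= Z:
        raise ValueError("surface indices must lie within [0, Z)")

    out = np.zeros_like(vol.data)
    for x in range(X):
        s = surface[x]
        out[: Z - s, x, :] = vol.data[s:, x, :]
    meta = dict(vol.meta)
    meta["flatten_shifts"] = surface.tolist()
    return ComplexOCEVolume(data=out, dz=vol.dz, dx=vol.dx, dt=vol.dt, meta=meta)


def extract_phase_stack(vol: ComplexOCEVolume, n_depths: int,
                        depth_offset: int = 0, depth_stride: int = 1,
                        unwrap_time: bool = False) -> PhaseStack:
    """Lag-1 phase differences for ``n_depths`` depth layers of a flattened volume.

    The phase image at depth z is ``arg(data[z,:,t+1] * conj(data[z,:,t]))``
    (Kasai-style conjugate product — wrap-safe, identical modulo 2π to
    subtracting frame phases), wrapped to [-pi, pi).  Layers are taken every
    ``depth_stride`` indices starting at ``depth_offset``.

    With ``unwrap_time`` the differences are additionally unwrapped along the
    time axis (stress-testing aid; the values then leave [-pi, pi) and are
    re-wrapped before storage).
    """
    if n_depths < 1:
        raise ValueError("n_depths must be >= 1")
    Z = vol.shape[0]
    last = depth_offset + (n_depths - 1) * depth_stride
    if last >= Z:
        raise ValueError(f"requested depths reach index {last}, volume has Z={Z}")

    sel = vol.data[depth_offset: last + 1: depth_stride]
    prod = sel[:, :, 1:] * np.conj(sel[:, :, :-1])
    phase = np.angle(prod)
    if unwrap_time:
        phase = np.unwrap(phase, axis=2)
    phase = np.mod(phase + np.pi, 2 * np.pi) - np.pi       # [-pi, pi)
    return PhaseStack(phase=phase, dz=vol.dz, dx=vol.dx, dt=vol.dt,
                      depth_offset=depth_offset, depth_stride=depth_stride,
                      meta=dict(vol.meta))
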