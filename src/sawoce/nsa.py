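"""Numerical Spectral Analysis: depth-resolved phase velocity from f–k spectra.

For each depth layer the lateral×temporal phase-difference image is apodized
with a separable Hann window, Fourier-transformed in 2-D, and magnitude-averaged
with its neighbours within ±`depth_radius` layers to form a stabilized spectral
energy map S(k, f).  The phase velocity is the ratio of the energy-weighted
spectral centroids,

    c = f_c / k_c,   f_c = Σ f·S / Σ S,   k_c = Σ k·S / Σ S,

taken over a region of interest around the excitation frequency.  Wavenumber k
is measured in cycles per metre throughout, so the ratio needs no 2π factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .core_io import PhaseStack, SpectralMap, VelocityProfile

__all__ = ["NSAConfig", "auto_roi", "spectral_map", "centroid_velocity",
           "nsa_profile", "complex_slice_stack"]

UM = 1e-6


class SpectrumError(RuntimeError):
    """Velocity is undefined for a spectral map (no energy / degenerate centroid)."""


@dataclass
class NSAConfig:
    """Tunable knobs of the spectral estimator.

    depth_radius:
        Layers magnitude-averaged on each side of the target depth (±2 default).
    pad_factor:
        FFT zero-padding multiplier (next power of two of pad_factor×size);
        reduces centroid quantization.
    roi_f, roi_k:
        Explicit region of interest (hertz / cycles-per-metre); when None both
        are derived from ``f0`` and the velocity search band via :func:`auto_roi`.
    c_min, c_max, band:
        Velocity search band (m/s) and relative frequency half-width used by
        the automatic ROI.
    centroid_threshold:
        Relative level (fraction of the ROI maximum) below which bins are
        excluded from the centroid: the centroid is taken over the *central*
        spectral energy, which suppresses the broadband noise floor and
        window-leakage tails that would otherwise drag the wavenumber
        centroid toward the ROI middle.
    smooth_window:
        rLOESS window (samples) used downstream; carried here so one config
        object describes the whole estimation stage.
    use_complex_field:
        Feed the complex M-scan slices to the 2-D FFT instead of the
        phase-difference slices.
    """

    depth_radius: int = 2
    pad_factor: int = 2
    roi_f: tuple[float, float] | None = None
    roi_k: tuple[float, float] | None = None
    c_min: float = 1.0
    c_max: float = 20.0
    band: float = 0.5
    centroid_threshold: float = 0.25
    smooth_window: int = 30
    use_complex_field: bool = False

    def __post_init__(self) -> None:
        if self.depth_radius < 0:
            raise ValueError("depth_radius must be >= 0")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")
        if not (0 < self.c_min < self.c_max):
            raise ValueError("need 0 < c_min < c_max")
        if not (0 < self.band < 1):
            raise ValueError("band must be in (0, 1)")
        if not (0 <= self.centroid_threshold < 1):
            raise ValueError("centroid_threshold must be in [0, 1)")
        for roi, name in ((self.roi_f, "roi_f"), (self.roi_k, "roi_k")):
            if roi is not None:
                lo, hi = roi
                if not (0 < lo < hi):
                    raise ValueError(f"{name} bounds must be positive and ordered")


def complex_slice_stack(vol, n_depths: int, depth_offset: int = 0,
                        depth_stride: int = 1) -> PhaseStack:
    """Build a stack whose spectra are taken on the complex M-scan field itself.

    The returned object still carries lag-1 phase differences in ``phase`` (so
    it remains a valid :class:`PhaseStack`), but stashes the matching complex
    slices for :func:`nsa_profile` with ``use_complex_field=True``.
    """
    from .preprocess import extract_phase_stack

    stack = extract_phase_stack(vol, n_depths, depth_offset=depth_offset,
                                depth_stride=depth_stride)
    last = depth_offset + (n_depths - 1) * depth_stride
    stack.meta["_complex_slices"] = vol.data[depth_offset: last + 1: depth_stride]
    return stack


def auto_roi(f0: float, c_min: float, c_max: float, band: float = 0.5
             ) -> tuple[tuple[float, float], tuple[float, float]]:
    """ROI brackets from the excitation frequency and a velocity search band.

    Frequencies span ``f0*(1±band)``; wavenumbers span the values a wave in
    ``[c_min, c_max]`` could produce inside that frequency band:
    ``k ∈ [f_min/c_max, f_max/c_min]``.

    Returns ``(roi_k, roi_f)`` in (cycles/m, Hz).
    """
    if not (0 < c_min < c_max):
        raise ValueError("need 0 < c_min < c_max")
    if not (0 < band < 1):
        raise ValueError("band must be in (0, 1)")
    f_lo, f_hi = f0 * (1 - band), f0 * (1 + band)
    return (f_lo / c_max, f_hi / c_min), (f_lo, f_hi)


def _resolve_roi(stack: PhaseStack, config: NSAConfig, f0: float | None
                 ) -> tuple[tuple[float, float], tuple[float, float]]:
    if config.roi_f is not None and config.roi_k is not None:
        return config.roi_k, config.roi_f
    if f0 is None:
        f0 = stack.meta.get("f0")
    if f0 is None:
        raise ValueError("automatic ROI needs the excitation frequency f0 "
                         "(pass f0= or set stack.meta['f0'])")
    return auto_roi(float(f0), config.c_min, config.c_max, config.band)


def _fft_size(n: int, pad_factor: int) -> int:
    return 1 << int(np.ceil(np.log2(pad_factor * n)))


def spectral_map(stack: PhaseStack, z: int, config: NSAConfig | None = None,
                 f0: float | None = None) -> SpectralMap:
    """Stabilized spectral energy map S(k, f) at one retained depth index.

    Every slice within ±`depth_radius` retained layers (truncated at the stack
    edges) is mean-removed, Hann-apodized along both lateral and temporal axes,
    2-D FFT'd with zero padding, and the magnitude maps are averaged.  The
    ``f >= 0`` half-plane is kept and, of the two wavenumber signs, the one
    carrying more ROI energy (a travelling wave concentrates in one); the map
    is then cropped to the ROI.
    """
    config = config or NSAConfig()
    roi_k, roi_f = _resolve_roi(stack, config, f0)
    return _windowed_average_spectrum(stack.phase, z, config, roi_k, roi_f,
                                      stack.dx, stack.dt)


def _windowed_average_spectrum(slices: np.ndarray, z: int, config: NSAConfig,
                               roi_k: tuple[float, float], roi_f: tuple[float, float],
                               dx: float, dt: float) -> SpectralMap:
    """Shared Hann-window + padded-FFT + magnitude-average core.

    ``slices`` may be the real phase-difference stack or the complex M-scan
    field (``use_complex_field``); the windowing and averaging are identical.
    """
    nz, X, T = slices.shape
    if not (0 <= z < nz):
        raise IndexError(f"depth index {z} outside stack of {nz} layers")
    lo, hi = max(0, z - config.depth_radius), min(nz - 1, z + config.depth_radius)
    if hi < lo:
        raise ValueError("empty depth window")

    win = np.outer(hann(X, sym=True), hann(T, sym=True))
    nk = _fft_size(X, config.pad_factor)
    nf = _fft_size(T, config.pad_factor)

    acc = np.zeros((nk, nf))
    for zz in range(lo, hi + 1):
        sl = slices[zz]
        sl = (sl - sl.mean()) * win
        acc += np.abs(np.fft.fft2(sl, s=(nk, nf)))
    S_full = np.fft.fftshift(acc / (hi - lo + 1))

    k_axis = np.fft.fftshift(np.fft.fftfreq(nk, d=dx * UM))   # cycles/m
    f_axis = np.fft.fftshift(np.fft.fftfreq(nf, d=dt))        # Hz
    f_sel = f_axis >= 0
    S_half = S_full[:, f_sel]
    f_half = f_axis[f_sel]

    f_in = (f_half >= roi_f[0]) & (f_half <= roi_f[1])
    k_pos = (k_axis >= roi_k[0]) & (k_axis <= roi_k[1])
    k_neg = (-k_axis >= roi_k[0]) & (-k_axis <= roi_k[1])
    e_pos = S_half[np.ix_(k_pos, f_in)].sum()
    e_neg = S_half[np.ix_(k_neg, f_in)].sum()
    if e_pos >= e_neg:
        S_roi = S_half[np.ix_(k_pos, f_in)]
        k_roi = k_axis[k_pos]
    else:
        S_roi = S_half[np.ix_(k_neg, f_in)][::-1, :]
        k_roi = -k_axis[k_neg][::-1]
    f_roi = f_half[f_in]
    if S_roi.size == 0:
        raise SpectrumError("ROI narrower than one padded FFT bin")
    return SpectralMap(S=S_roi, k_axis=k_roi, f_axis=f_roi,
                       roi=(roi_k[0], roi_k[1], roi_f[0], roi_f[1]))


def centroid_velocity(S: SpectralMap, central_threshold: float = 0.0) -> float:
    """Weighted-spectral-centroid phase velocity c = f_c / k_c, m/s.

    f_c and k_c are the energy-weighted mean frequency and wavenumber of the
    map.  With ``central_threshold`` > 0 only the central spectral energy —
    bins at or above that fraction of the map maximum — enters the centroid.
    Positive-scale invariant; undefined when the map holds no energy or the
    wavenumber centroid vanishes.
    """
    M = S.S
    if central_threshold > 0 and M.size:
        M = np.where(M >= central_threshold * M.max(), M, 0.0)
    total = M.sum()
    if total <= 0:
        raise SpectrumError("zero total energy in ROI")
    k_c = float((S.k_axis[:, None] * M).sum() / total)
    f_c = float((S.f_axis[None, :] * M).sum() / total)
    if k_c == 0:
        raise SpectrumError("degenerate spectrum: wavenumber centroid is zero")
    return f_c / k_c


def nsa_profile(stack: PhaseStack, config: NSAConfig | None = None,
                f0: float | None = None, max_fail_frac: float = 0.5) -> VelocityProfile:
    """Raw depth-resolved velocity profile: one centroid estimate per layer.

    Depths whose spectrum is degenerate are recorded as NaN; if more than
    ``max_fail_frac`` of the layers fail the whole profile is rejected.
    Smoothing (rLOESS) is a separate, downstream step.
    """
    config = config or NSAConfig()
    roi_k, roi_f = _resolve_roi(stack, config, f0)
    if config.use_complex_field:
        field = stack.meta.get("_complex_slices")
        if field is None:
            raise ValueError("use_complex_field requires a stack built by "
                             "complex_slice_stack()")
        slices = field
    else:
        slices = stack.phase
    nz = slices.shape[0]
    v = np.full(nz, np.nan)
    for z in range(nz):
        try:
            S = _windowed_average_spectrum(slices, z, config, roi_k, roi_f,
                                           stack.dx, stack.dt)
            v[z] = centroid_velocity(S, config.centroid_threshold)
        except SpectrumError:
            pass
    n_fail = int(np.isnan(v).sum())
    if n_fail > max_fail_frac * nz:
        raise RuntimeError(f"velocity undefined at {n_fail}/{nz} depths")
    v_true = None
    return VelocityProfile(depth_index=stack.depth_indices(), dz=stack.dz,
                           v_raw=v, v_true=v_true)
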