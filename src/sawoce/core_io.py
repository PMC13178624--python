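"""Domain containers and on-disk formats shared by every pipeline stage.

The package operates on three-dimensional complex optical-coherence-elastography
(OCE) volumes indexed ``[z, x, t]`` (axial depth, lateral position, time), on
stacks of lag-1 phase-difference images, on frequency–wavenumber spectral energy
maps, and on depth-resolved phase-velocity profiles.  Volumes travel as HDF5
(paired ``/real`` + ``/imag`` float64 datasets), profiles as CSV, and bilinear
interface fits as JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ComplexOCEVolume",
    "PhaseStack",
    "SpectralMap",
    "VelocityProfile",
    "BilinearFit",
    "SchemaError",
    "write_volume",
    "read_volume",
    "write_profile",
    "read_profile",
    "read_fit",
]


class SchemaError(ValueError):
    """An on-disk artifact is missing a dataset/attribute or violates an invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class ComplexOCEVolume:
    """Complex OCT field ``data[z, x, t]`` with physical axis spacings.

    Parameters
    ----------
    data:
        Complex scalar field, axes (axial depth, lateral position, time frame).
    dz, dx:
        Axial / lateral pixel spacing in micrometres.
    dt:
        Frame interval in seconds.
    meta:
        Free-form provenance (excitation frequency, simulation seed, ...).
    """

    data: np.ndarray
    dz: float
    dx: float
    dt: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _require(self.data.ndim == 3, f"volume must have 3 axes, got {self.data.ndim}")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        _require(self.dz > 0 and self.dx > 0 and self.dt > 0,
                 "dz, dx, dt must all be positive")
        _require(bool(np.isfinite(self.data.real).all() and np.isfinite(self.data.imag).all()),
                 "volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class PhaseStack:
    """Per-depth lateral×temporal phase-difference images, radians in [-pi, pi).

    ``phase[z, x, t]`` is the lag-1 phase difference between frames ``t+1`` and
    ``t`` of the source volume; the temporal extent is therefore one less than
    the volume's.  ``depth_offset`` is the volume depth index of the first
    retained layer and ``depth_stride`` the spacing between retained layers.
    """

    phase: np.ndarray
    dz: float
    dx: float
    dt: float
    depth_offset: int = 0
    depth_stride: int = 1
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        _require(self.phase.ndim == 3, "phase stack must have 3 axes")
        _require(bool((self.phase >= -np.pi).all() and (self.phase < np.pi).all()),
                 "phase values must lie in [-pi, pi)")
        _require(self.depth_offset >= 0 and self.depth_stride >= 1,
                 "depth_offset must be >= 0 and depth_stride >= 1")

    @property
    def n_depths(self) -> int:
        return self.phase.shape[0]

    def depth_indices(self) -> np.ndarray:
        """Volume depth indices of the retained layers."""
        return self.depth_offset + self.depth_stride * np.arange(self.n_depths)


@dataclass
class SpectralMap:
    """Nonnegative spectral energy ``S[k, f]`` on a wavenumber×frequency grid.

    k is in cycles per metre, f in hertz; ``roi`` records the
    (k_min, k_max, f_min, f_max) rectangle the map was restricted to.
    """

    S: np.ndarray
    k_axis: np.ndarray
    f_axis: np.ndarray
    roi: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        self.k_axis = np.asarray(self.k_axis, dtype=np.float64)
        self.f_axis = np.asarray(self.f_axis, dtype=np.float64)
        _require(self.S.ndim == 2, "S must be 2-D [k, f]")
        _require(self.S.shape == (self.k_axis.size, self.f_axis.size),
                 "S shape must match axis lengths")
        _require(bool((self.S >= 0).all()), "spectral energy must be nonnegative")
        for ax, name in ((self.k_axis, "k_axis"), (self.f_axis, "f_axis")):
            if ax.size > 1:
                _require(bool((np.diff(ax) > 0).all()), f"{name} must be strictly increasing")
        k_min, k_max, f_min, f_max = self.roi
        _require(k_min < k_max and f_min < f_max, "roi bounds must be ordered")


@dataclass
class VelocityProfile:
    """Depth-resolved phase velocity: raw, optionally smoothed, optionally true.

    ``depth_um[i] == depth_index[i] * dz`` always holds; ``v_raw`` may contain
    NaN at depths where estimation failed, but is positive where defined.
    """

    depth_index: np.ndarray
    dz: float
    v_raw: np.ndarray | None = None
    v_smooth: np.ndarray | None = None
    v_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth_index = np.asarray(self.depth_index, dtype=np.int64)
        _require(self.depth_index.size > 0, "profile must be non-empty")
        _require(self.dz > 0, "dz must be positive")
        _require(bool((np.diff(self.depth_index) > 0).all()) if self.depth_index.size > 1 else True,
                 "depth indices must be strictly increasing")
        n = self.depth_index.size
        for name in ("v_raw", "v_smooth", "v_true"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=np.float64)
            _require(v.shape == (n,), f"{name} length must match depth_index")
            defined = np.isfinite(v)
            _require(bool((v[defined] > 0).all()), f"{name} must be positive where defined")
            setattr(self, name, v)

    @property
    def depth_um(self) -> np.ndarray:
        return self.depth_index * self.dz

    def __len__(self) -> int:
        return self.depth_index.size


@dataclass
class BilinearFit:
    """Two independent line segments v = a*z + b with a free breakpoint.

    The upper segment covers depth indices ``z < z_break``, the lower segment
    ``z >= z_break``; a velocity discontinuity (``jump``) is allowed at the
    breakpoint.  ``sse`` is the total sum of squared errors of the two-segment
    fit and can never exceed ``sse_single``, the SSE of the best single line.
    """

    a1: float
    b1: float
    a2: float
    b2: float
    z_break: int
    jump: float
    sse: float
    sse_single: float

    def __post_init__(self) -> None:
        _require(self.sse <= self.sse_single + 1e-9 * max(1.0, self.sse_single),
                 "bilinear SSE cannot exceed single-line SSE")

    def predict(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        return np.where(z < self.z_break, self.a1 * z + self.b1, self.a2 * z + self.b2)

    def to_dict(self) -> dict[str, float]:
        d = dataclasses.asdict(self)
        d["z_break"] = int(self.z_break)
        return d


# ---------------------------------------------------------------------------
# HDF5 volume I/O


def write_volume(vol: ComplexOCEVolume, path: str | Path,
                 compression: str | None = None) -> None:
    """Write a volume as HDF5: /real, /imag float64 + dz_um/dx_um/dt_s/meta_json attrs.

    Round-trips bit-exactly through :func:`read_volume`.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        kw = {"compression": compression} if compression else {}
        f.create_dataset("real", data=vol.data.real.astype(np.float64), **kw)
        f.create_dataset("imag", data=vol.data.imag.astype(np.float64), **kw)
        f.attrs["dz_um"] = float(vol.dz)
        f.attrs["dx_um"] = float(vol.dx)
        f.attrs["dt_s"] = float(vol.dt)
        f.attrs["meta_json"] = json.dumps(vol.meta, sort_keys=True, default=_json_default)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_volume(path: str | Path) -> ComplexOCEVolume:
    """Read a volume written by :func:`write_volume`, validating the schema."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for ds in ("real", "imag"):
            if ds not in f:
                raise SchemaError(f"{path}: missing dataset /{ds}")
        for attr in ("dz_um", "dx_um", "dt_s"):
            if attr not in f.attrs:
                raise SchemaError(f"{path}: missing attribute {attr}")
        data = np.asarray(f["real"]) + 1j * np.asarray(f["imag"])
        meta = json.loads(f.attrs.get("meta_json", "{}"))
        return ComplexOCEVolume(data=data, dz=float(f.attrs["dz_um"]),
                                dx=float(f.attrs["dx_um"]), dt=float(f.attrs["dt_s"]),
                                meta=meta)


# ---------------------------------------------------------------------------
# Profile CSV + fit JSON I/O


_PROFILE_COLUMNS = ["depth_index", "depth_um", "v_raw", "v_smooth", "v_true"]


def write_profile(profile: VelocityProfile, path: str | Path,
                  fit: BilinearFit | None = None) -> None:
    """Write a velocity profile as CSV; a bilinear fit goes to a ``.fit.json`` sidecar.

    Columns: depth_index, depth_um, v_raw, v_smooth, v_true (blank when absent).
    """
    path = Path(path)
    n = len(profile)
    cols: dict[str, Any] = {
        "depth_index": profile.depth_index,
        "depth_um": profile.depth_um,
    }
    for name in ("v_raw", "v_smooth", "v_true"):
        v = getattr(profile, name)
        cols[name] = v if v is not None else np.full(n, np.nan)
    pd.DataFrame(cols, columns=_PROFILE_COLUMNS).to_csv(path, index=False,
                                                        float_format="%.9g")
    if fit is not None:
        fit_path = path.with_suffix(".fit.json")
        fit_path.write_text(json.dumps(fit.to_dict(), indent=2, sort_keys=True) + "\n")


def read_profile(path: str | Path, dz: float | None = None) -> VelocityProfile:
    """Read a profile CSV back; dz is recovered from the depth_um column unless given."""
    df = pd.read_csv(path)
    for col in _PROFILE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col}")
    if dz is None:
        idx = df["depth_index"].to_numpy()
        nz = idx != 0
        if not nz.any():
            raise SchemaError(f"{path}: cannot recover dz from a single zero-index row")
        dz = float(np.median(df["depth_um"].to_numpy()[nz] / idx[nz]))

    def _chan(name: str) -> np.ndarray | None:
        v = df[name].to_numpy(dtype=np.float64)
        return None if np.isnan(v).all() else v

    return VelocityProfile(depth_index=df["depth_index"].to_numpy(), dz=dz,
                           v_raw=_chan("v_raw"), v_smooth=_chan("v_smooth"),
                           v_true=_chan("v_true"))


def read_fit(path: str | Path) -> BilinearFit:
    d = json.loads(Path(path).read_text())
    try:
        return BilinearFit(**{k: d[k] for k in
                              ("a1", "b1", "a2", "b2", "z_break", "jump", "sse", "sse_single")})
    except KeyError as e:  # pragma: no cover - defensive
        raise SchemaError(f"{path}: missing fit field {e}") from e
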