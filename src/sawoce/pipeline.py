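"""End-to-end orchestration: simulate/load → flatten → NSA → interface → (DLI).

Stages communicate only through the documented file formats (HDF5 volume, CSV
profile, JSON fit), so every stage is independently runnable and testable; the
orchestrator wires them together from one YAML config, records a manifest
(config, seeds, versions) and writes a human-readable summary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .core_io import read_volume, write_profile, write_volume
from .interface import detect_interface, rloess_smooth
from .nsa import NSAConfig, nsa_profile
from .preprocess import detect_surface, extract_phase_stack, flatten_volume
from .simulate import SimulationConfig, default_config, simulate_volume, small_config, true_profile

__all__ = ["run_pipeline", "load_pipeline_config", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


def load_pipeline_config(path: str | Path) -> dict[str, Any]:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise PipelineError("config: YAML root must be a mapping")
    return cfg


def _build_sim_config(block: dict[str, Any], seed: int) -> SimulationConfig:
    block = dict(block)
    preset = block.pop("preset", "small")
    if "layers" in block:
        block["layers"] = tuple(tuple(l) for l in block["layers"])
    if "shape" in block:
        block["shape"] = tuple(block["shape"])
    block.setdefault("seed", seed)
    factory = {"small": small_config, "full": default_config}.get(preset)
    if factory is None:
        raise PipelineError(f"simulate: unknown preset {preset!r}")
    return factory(**block)


def _stage(name: str):
    def wrap(fn):
        def inner(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise PipelineError(f"[{name}] {e}") from e
        return inner
    return wrap


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Execute the configured stages, writing all artifacts under ``outdir``.

    Returns a result dictionary with the profile, fit verdict and artifact
    paths.  Partial artifacts are retained when a stage fails.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    result: dict[str, Any] = {"outdir": str(outdir)}

    # --- acquire -----------------------------------------------------------
    sim_cfg = None
    if "simulate" in config:
        sim_cfg = _stage("simulate")(_build_sim_config)(config["simulate"], seed)
        vol = _stage("simulate")(simulate_volume)(sim_cfg)
        write_volume(vol, outdir / "volume.h5")
    elif "volume" in config:
        vol = _stage("load")(read_volume)(config["volume"])
    else:
        raise PipelineError("config: need either a 'simulate' block or a 'volume' path")

    # --- preprocess --------------------------------------------------------
    surface = _stage("preprocess")(detect_surface)(vol)
    flat = _stage("preprocess")(flatten_volume)(vol, surface)
    np.savetxt(outdir / "surface.csv", surface, fmt="%d", header="surface_index")
    usable = vol.shape[0] - int(surface.max())
    n_depths = int(config.get("n_depths", min(100, usable - 1)))
    stack = _stage("preprocess")(extract_phase_stack)(flat, n_depths)

    # --- nsa ---------------------------------------------------------------
    nsa_cfg = NSAConfig(**config.get("nsa", {}))
    profile = _stage("nsa")(nsa_profile)(stack, nsa_cfg)
    if sim_cfg is not None:
        profile.v_true = true_profile(sim_cfg, n_depths).v_true

    # --- interface ---------------------------------------------------------
    icfg = dict(config.get("interface", {}))
    window = int(icfg.pop("window", nsa_cfg.smooth_window))
    profile = _stage("interface")(rloess_smooth)(profile, window)
    verdict = _stage("interface")(detect_interface)(profile, **icfg)
    write_profile(profile, outdir / "profile.csv", fit=verdict.fit)

    # --- optional deep-learning inversion ----------------------------------
    if config.get("pvnet", {}).get("enabled", False):
        result["pvnet"] = _stage("pvnet")(_run_dli)(config["pvnet"], stack, profile,
                                                    outdir, seed)

    manifest = {
        "sawoce_version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "simulation": _jsonable(dataclasses.asdict(sim_cfg)) if sim_cfg else None,
        "numpy_version": np.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    summary = _summarize(profile, verdict)
    (outdir / "summary.txt").write_text(summary)
    result.update({"profile": profile, "verdict": verdict, "summary": summary})
    return result


def _run_dli(block: dict[str, Any], stack, profile, outdir: Path, seed: int
             ) -> dict[str, Any]:
    """Train PVNet on this run's phase images, labelled per the DLI protocol:
    the rLOESS-smoothed spectral estimates serve as ground truth (or the
    simulator's true velocities with ``labels: true``)."""
    from .pvnet import PVNetConfig, TrainingConfig, evaluate_mae, train, write_profile_from_predictions

    block = dict(block)
    block.pop("enabled", None)
    label_mode = block.pop("labels", "nsa")
    variant = block.pop("variant", "tiny")
    mcfg = PVNetConfig.preset(variant)
    tkeys = {f.name for f in dataclasses.fields(TrainingConfig)}
    tcfg = TrainingConfig(seed=seed, **{k: v for k, v in block.items() if k in tkeys})

    labels = profile.v_smooth if label_mode == "nsa" else profile.v_true
    if labels is None:
        raise ValueError(f"no labels available for mode {label_mode!r}")
    ok = np.isfinite(labels)
    model, history = train(stack.phase[ok], labels[ok], tcfg, mcfg)
    mae, mae_std = evaluate_mae(model, stack.phase[ok], labels[ok])
    preds = model.predict(stack.phase)
    write_profile_from_predictions(stack, preds, outdir / "pvnet_profile.csv")
    (outdir / "pvnet_history.json").write_text(json.dumps(history))
    return {"mae": mae, "mae_std": mae_std, "epochs": len(history["val_loss"])}


def _summarize(profile, verdict) -> str:
    lines = ["sawoce pipeline summary", "======================="]
    fit = verdict.fit
    v = profile.v_smooth if profile.v_smooth is not None else profile.v_raw
    if verdict.has_interface:
        upper = np.nanmedian(v[: max(fit.z_break - profile.depth_index[0], 1)])
        lower = np.nanmedian(v[fit.z_break - profile.depth_index[0]:])
        lines += [
            f"interface detected at depth index {fit.z_break} "
            f"({verdict.depth_mm:.3f} mm)",
            f"velocity jump at interface: {fit.jump:.2f} m/s",
            f"upper-layer median velocity: {upper:.2f} m/s",
            f"lower-layer median velocity: {lower:.2f} m/s",
        ]
    else:
        lines += [
            f"no interface detected ({verdict.reason})",
            f"median velocity: {np.nanmedian(v):.2f} m/s",
        ]
    lines += [f"bilinear fit SSE {fit.sse:.4g} vs single-line {fit.sse_single:.4g}"]
    return "\n".join(lines) + "\n"


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
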