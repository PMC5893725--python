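"""End-to-end pipeline driver: phantom → preprocess → segment → metrics →
conduct → stats, with a reproducibility manifest.

Configuration is a nested dict (typically loaded from YAML) with one
block per stage; unknown keys are rejected so typos fail fast.  Every
stage writes its outputs under its own subdirectory of the run folder
and never mutates the inputs of an earlier stage.  The manifest records
a hash of the configuration, the package version and a checksum per
output file, so re-running a deterministic configuration reproduces
identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__, io, metrics, phantom, preprocess, segment, stats
from .conduct import conductivity_tensor, verify_blocks

log = logging.getLogger("cardiohomog")

_STAGES = ("phantom", "preprocess", "segment", "metrics", "conduct", "stats")

_ALLOWED_KEYS = {
    "phantom": {"grid_shape", "voxel_size", "target_fractions", "myocyte_height",
                "myocyte_width", "interstitial_thickness", "layers_per_lamina",
                "capillary_radius", "rotation_angle", "attenuation_rate",
                "psf_sigma", "noise_sd", "shot_noise"},
    "preprocess": {"gaussian_sigma", "mean_radius", "attenuation_rate",
                   "laser_slope", "fit_attenuation", "rl_iterations"},
    "segment": {"low_wga_threshold", "wga_interface_k", "vessel_dilation",
                "nucleus_min_volume", "proximity_radius", "cleft_min_volume",
                "cleft_wga_threshold", "min_myocyte_volume",
                "min_myocyte_half_thickness", "capillary_radius"},
    "metrics": {"normalize"},
    "conduct": {"sigma_bulk", "rtol", "use_interface_addition", "verify",
                "verify_blocks", "verify_grid"},
    "stats": {"alpha", "equal_var"},
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated stage-parameter blocks plus run-level settings."""

    stages: Dict[str, dict] = field(default_factory=dict)
    seed: int = 0
    skip: List[str] = field(default_factory=list)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        seed = raw.pop("seed", 0)
        skip = raw.pop("skip", [])
        log_level = raw.pop("log_level", "INFO")
        if not isinstance(seed, int):
            raise ConfigError("seed must be an integer")
        unknown = set(raw) - set(_STAGES)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        stages = {}
        for name in _STAGES:
            block = raw.get(name, {}) or {}
            bad = set(block) - _ALLOWED_KEYS[name]
            if bad:
                raise ConfigError(
                    f"unknown keys in [{name}]: {sorted(bad)}")
            stages[name] = block
        for s in skip:
            if s not in _STAGES:
                raise ConfigError(f"cannot skip unknown stage {s!r}")
        return cls(stages=stages, seed=seed, skip=list(skip),
                   log_level=log_level)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {"stages": config.stages, "seed": config.seed, "skip": config.skip},
        sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest.

    A stage failure halts the run with the stage name in the raised
    error; outputs of completed stages are retained on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    state: dict = {}
    for name in _STAGES:
        if name in config.skip:
            manifest["stages"][name] = {"status": "skipped"}
            continue
        stage_dir = outdir / name
        stage_dir.mkdir(exist_ok=True)
        t0 = time.time()
        try:
            outputs = _run_stage(name, config, state, stage_dir)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        entry = {
            "status": "complete",
            "seconds": round(time.time() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        entry.update(state.get(f"{name}_summary", {}))
        manifest["stages"][name] = entry
        log.info("stage %s complete (%.2fs)", name, entry["seconds"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _run_stage(name: str, config: PipelineConfig, state: dict,
               stage_dir: Path) -> List[Path]:
    params = dict(config.stages.get(name, {}))
    if name == "phantom":
        render_keys = {"attenuation_rate", "psf_sigma", "noise_sd", "shot_noise"}
        render_kwargs = {k: params.pop(k) for k in list(params)
                         if k in render_keys}
        if "grid_shape" in params:
            params["grid_shape"] = tuple(params["grid_shape"])
        if "psf_sigma" in render_kwargs:
            render_kwargs["psf_sigma"] = tuple(render_kwargs["psf_sigma"])
        spec = phantom.PhantomSpec(seed=config.seed, **params)
        labels = phantom.generate_labels(spec)
        stack = phantom.render_channels(labels, seed=config.seed,
                                        **render_kwargs)
        state["truth_labels"] = labels
        state["raw_stack"] = stack
        state["phantom_summary"] = {"achieved": labels.meta.get("achieved")}
        return [io.write_labels(labels, stage_dir / "truth_labels.tif"),
                io.write_stack(stack, stage_dir / "raw_stack.tif")]
    if name == "preprocess":
        stack = preprocess.preprocess_stack(state["raw_stack"], **params)
        state["stack"] = stack
        return [io.write_stack(stack, stage_dir / "preprocessed.tif")]
    if name == "segment":
        stack = state.get("stack", state.get("raw_stack"))
        seg_params = segment.SegmentationParams(
            voxel_size=stack.voxel_size, **params)
        labels = segment.segment_volume(stack, seg_params)
        state["labels"] = labels
        state["seg_params"] = seg_params
        return [io.write_labels(labels, stage_dir / "segmented_labels.tif")]
    if name == "metrics":
        labels = state.get("labels", state.get("truth_labels"))
        vf = metrics.volume_fractions(labels)
        state["fractions"] = vf
        frame = pd.DataFrame([vf.as_dict()])
        path = stage_dir / "fractions.csv"
        frame.to_csv(path, index=False)
        state["metrics_summary"] = {"fractions": vf.as_dict()}
        return [path]
    if name == "conduct":
        labels = state.get("labels", state.get("truth_labels"))
        kwargs = {k: params[k] for k in ("sigma_bulk", "rtol") if k in params}
        addition = None
        if params.get("use_interface_addition") and "stack" in state:
            seg_params = state.get("seg_params")
            k = seg_params.wga_interface_k if seg_params else 1.0
            addition = segment.refine_interface(
                labels.mask(1), state["stack"]["WGA"], k=k)
        tensor = conductivity_tensor(labels, addition, **kwargs)
        out = {"tensor": tensor.as_dict(),
               "residuals": tensor.residuals,
               "iterations": tensor.iterations}
        if params.get("verify"):
            grid = tuple(params.get("verify_grid", (40, 40, 40)))
            blocks = [tuple(tuple(p) for p in b)
                      for b in params.get("verify_blocks",
                                          [[[8, 24], [0, grid[1]], [8, 24]]])]
            report = verify_blocks(blocks, grid,
                                   rtol=params.get("rtol", 1e-10))
            out["verification"] = {
                "max_abs_error": report["max_abs_error"],
                "directions": {d: report[d] for d in ("l", "t", "n")},
            }
        state["tensor"] = tensor
        state["conduct_summary"] = {"sigma": tensor.as_dict()}
        path = stage_dir / "conductivity.json"
        path.write_text(json.dumps(out, indent=2))
        return [path]
    if name == "stats":
        vf = state.get("fractions")
        tensor = state.get("tensor")
        rows = []
        if vf is not None:
            rows.append({"quantity": "V_e", "value": vf.V_e})
            rows.append({"quantity": "V_cleft", "value": vf.V_cleft})
        if tensor is not None:
            for d in ("l", "t", "n"):
                rows.append({"quantity": f"sigma_{d}", "value": tensor.sigma(d)})
        frame = pd.DataFrame(rows)
        path = stage_dir / "summary.csv"
        frame.to_csv(path, index=False)
        return [path]
    raise ConfigError(f"unknown stage {name!r}")
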