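"""Configured end-to-end runs: simulate -> correlate -> fit -> downstream.

A run is described by a TOML file with one table per stage; ``run_pipeline``
executes the stages in order, writes one JSON result per stage plus a
manifest (package version, seeds, input hashes), and aborts with a
stage-named error on failure, retaining partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np

from . import __version__
from .correlate import multi_tau_correlate, per_lag_spread
from .fccs import (
    ConcentrationTriple,
    DetectionCalibration,
    forward_amplitudes,
    invert_amplitudes,
    kd_point,
)
from .models import FCSModelSpec, fit_fcs
from .presets import CALIBRATION, FCS_PRESETS, FRAP_PRESETS, fcs_preset_params
from .frap import FRAPCurve, fit_recovery
from .synthetic import (
    ColocGroundTruth,
    FCSSimConfig,
    generate_model_acf,
    simulate_fcs_traces,
    simulate_frap_curve,
    simulate_stack_pair,
)
from .coloc import ColocParams, map_source_target
from . import io as fio

__all__ = ["PipelineError", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage, original):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def load_config(path) -> dict:
    with open(path, "rb") as f:
        return tomllib.load(f)


def _hash_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute the stages named in ``config``; return the manifest.

    Recognized stage tables: ``[simulate_fcs]``, ``[correlate]``,
    ``[fit_fcs]``, ``[fccs]``, ``[frap]``, ``[coloc]``.  Input paths are
    validated before any computation runs.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = {"version": __version__, "seed": seed, "stages": [], "inputs": {}}

    # pre-flight: every referenced input must exist
    for stage_cfg in config.values():
        if isinstance(stage_cfg, dict):
            for key, val in stage_cfg.items():
                if key.endswith(("_file", "_path")) or key == "input":
                    if not Path(val).exists():
                        raise FileNotFoundError(f"configured input not found: {val}")
                    manifest["inputs"][str(val)] = _hash_file(val)

    state: dict = {}

    def _run(stage, fn):
        if stage not in config:
            return
        try:
            payload = fn(config[stage])
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(stage, exc) from exc
        fio.write_result(stage, payload, outdir / f"{stage}.json", seed=seed)
        manifest["stages"].append(stage)

    def simulate_fcs(cfg):
        sim = FCSSimConfig(**{**cfg, "seed": cfg.get("seed", seed)})
        traces, truth = simulate_fcs_traces(sim)
        fio.write_traces_hdf5(traces, outdir / "traces.h5")
        state["traces"] = traces
        return {"truth": truth, "traces_file": "traces.h5"}

    def correlate(cfg):
        traces = state.get("traces")
        if traces is None:
            traces = fio.read_traces_hdf5(cfg["input"])
        curve = per_lag_spread(traces[0], n_segments=cfg.get("n_segments", 10))
        fio.write_curve(curve, outdir / "curve.csv")
        state["curve"] = curve
        return {"n_lags": int(curve.lags.size), "curve_file": "curve.csv"}

    def fit_stage(cfg):
        curve = state.get("curve")
        if curve is None:
            curve = fio.read_curve(cfg["input"])
        spec = FCSModelSpec.parse(cfg.get("model", "3d1p1t"))
        fit = fit_fcs(curve, spec, CALIBRATION, seed=seed)
        return fit.to_dict()

    def fccs_stage(cfg):
        preset = cfg.get("concentrations", [40.0, 70.0, 25.0])
        calib = DetectionCalibration()
        conc = ConcentrationTriple(*preset)
        amps = forward_amplitudes(conc, calib)
        inv = invert_amplitudes(amps, calib)
        return {
            "amplitudes": {"G_G0": amps.G_G0, "G_R0": amps.G_R0, "G_x0": amps.G_x0},
            "concentrations_nM": {"Cg": inv.Cg, "Cr": inv.Cr, "Cgr": inv.Cgr},
            "Kd_nM": kd_point(inv),
        }

    def frap_stage(cfg):
        name = cfg.get("preset", "wnt3")
        sim = simulate_frap_curve(FRAP_PRESETS[name])
        curve = FRAPCurve(sim.time, sim.intensity, sim.n_prebleach, sim.bleach_radius)
        return fit_recovery(curve).to_dict()

    def coloc_stage(cfg):
        truth = ColocGroundTruth(seed=cfg.get("seed", seed),
                                 colocalized_fraction=cfg.get("colocalized_fraction", 0.5))
        green, red, labels = simulate_stack_pair(truth)
        source, target, result = map_source_target(green, red, truth.voxel_size)
        fio.write_stack(source.astype(np.uint8), outdir / "source_mask.tif")
        fio.write_stack(target.astype(np.uint8), outdir / "target_mask.tif")
        return dict(result.summary)

    _run("simulate_fcs", simulate_fcs)
    _run("correlate", correlate)
    _run("fit_fcs", fit_stage)
    _run("fccs", fccs_stage)
    _run("frap", frap_stage)
    _run("coloc", coloc_stage)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
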