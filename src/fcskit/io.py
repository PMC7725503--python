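"""Readers and writers for traces, curves, stacks and result JSON.

Dialects:

* traces — two-column CSV (``time_s``, ``counts``) per channel, or one HDF5
  file with a ``time`` dataset plus one ``counts_<channel>`` dataset per
  channel;
* correlation curves — CSV with columns ``lag_s``, ``G``, optional ``sd``,
  ``channel_pair``;
* image stacks — multi-page grayscale TIFF, z-major page order;
* calibrations and results — JSON validated against pydantic schemas
  (exported by :func:`result_schema`).

All writes round-trip: integers exactly, floats to 64-bit precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel

from .correlate import CorrelationCurve, IntensityTrace
from .fccs import DetectionCalibration
from .models import ConfocalCalibration

__all__ = [
    "FormatError",
    "read_trace_csv",
    "write_trace_csv",
    "read_traces_hdf5",
    "write_traces_hdf5",
    "read_curve",
    "write_curve",
    "read_stack",
    "write_stack",
    "read_confocal_calibration",
    "write_confocal_calibration",
    "read_detection_calibration",
    "write_result",
    "result_schema",
]


class FormatError(ValueError):
    """Input file does not conform to the documented dialect."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def read_trace_csv(path, channel: str = "G") -> IntensityTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_s", "counts"], path)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need >= 2 rows")
    bin_time = float(np.median(np.diff(t)))
    return IntensityTrace(bin_time=bin_time, counts=df["counts"].to_numpy(dtype=np.int64),
                          channel=channel)


def write_trace_csv(trace: IntensityTrace, path) -> None:
    t = trace.bin_time * np.arange(trace.counts.size)
    pd.DataFrame({"time_s": t, "counts": trace.counts}).to_csv(path, index=False)


def write_traces_hdf5(traces, path) -> None:
    with h5py.File(path, "w") as f:
        n = traces[0].counts.size
        f.create_dataset("time", data=traces[0].bin_time * np.arange(n))
        f.attrs["bin_time_s"] = traces[0].bin_time
        for tr in traces:
            f.create_dataset(f"counts_{tr.channel}", data=tr.counts)


def read_traces_hdf5(path) -> list[IntensityTrace]:
    traces = []
    with h5py.File(path, "r") as f:
        if "time" not in f:
            raise FormatError(f"{path}: missing 'time' dataset")
        bin_time = float(f.attrs.get("bin_time_s") or np.median(np.diff(f["time"][:])))
        for name in f:
            if name.startswith("counts_"):
                traces.append(
                    IntensityTrace(bin_time=bin_time, counts=f[name][:],
                                   channel=name.removeprefix("counts_"))
                )
    if not traces:
        raise FormatError(f"{path}: no 'counts_<channel>' datasets")
    return traces


def write_curve(curve: CorrelationCurve, path) -> None:
    data = {"lag_s": curve.lags, "G": curve.G}
    if curve.sd is not None:
        data["sd"] = curve.sd
    df = pd.DataFrame(data)
    df["channel_pair"] = curve.channel_pair
    # %.17g round-trips IEEE doubles through text exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_curve(path) -> CorrelationCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["lag_s", "G"], path)
    sd = df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None
    pair = str(df["channel_pair"].iloc[0]) if "channel_pair" in df.columns else "GG"
    return CorrelationCurve(lags=df["lag_s"].to_numpy(dtype=float),
                            G=df["G"].to_numpy(dtype=float), sd=sd, channel_pair=pair)


def write_stack(volume: np.ndarray, path) -> None:
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise FormatError("stack must be 3-D (z, y, x)")
    tifffile.imwrite(path, volume, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    vol = tifffile.imread(path)
    if vol.ndim == 2:
        vol = vol[None]
    if vol.ndim != 3:
        raise FormatError(f"{path}: expected a multi-page grayscale TIFF, "
                          f"got shape {vol.shape}")
    return vol


class ConfocalCalibrationModel(BaseModel):
    omega_xy_um: float
    omega_z_um: float
    K: float
    V_eff_fL: float
    dye_D_ref_um2_s: float


def write_confocal_calibration(calib: ConfocalCalibration, path) -> None:
    model = ConfocalCalibrationModel(
        omega_xy_um=calib.omega_xy,
        omega_z_um=calib.omega_z,
        K=calib.K,
        V_eff_fL=calib.V_eff_fL,
        dye_D_ref_um2_s=calib.dye_D_ref,
    )
    Path(path).write_text(model.model_dump_json(indent=2))


def read_confocal_calibration(path) -> ConfocalCalibration:
    try:
        model = ConfocalCalibrationModel.model_validate_json(Path(path).read_text())
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return ConfocalCalibration(omega_xy=model.omega_xy_um, omega_z=model.omega_z_um,
                               dye_D_ref=model.dye_D_ref_um2_s)


def read_detection_calibration(path) -> DetectionCalibration:
    data = json.loads(Path(path).read_text())
    try:
        return DetectionCalibration(**data)
    except TypeError as exc:
        raise FormatError(f"{path}: {exc}") from exc


class ResultEnvelope(BaseModel):
    """Envelope common to every result JSON the pipeline writes."""

    stage: str
    units: dict = {
        "length": "um",
        "time": "s",
        "rate": "Hz",
        "concentration": "nM",
        "diffusion": "um2/s",
    }
    seed: Optional[int] = None
    payload: dict


def write_result(stage: str, payload: dict, path, seed: Optional[int] = None) -> None:
    env = ResultEnvelope(stage=stage, seed=seed, payload=_jsonable(payload))
    Path(path).write_text(env.model_dump_json(indent=2))


def result_schema() -> dict:
    """JSON schema every result file validates against."""
    return ResultEnvelope.model_json_schema()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj
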