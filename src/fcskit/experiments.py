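"""Desk-scale replication experiments over the study fixtures.

Each function regenerates synthetic inputs from a named fixture, runs the
corresponding analysis stage, and returns the recovered quantities.  These
are the computations behind the analysis scripts and the replication
summary; they are deliberately small enough to run in seconds on one CPU.
"""

from __future__ import annotations

import numpy as np

from .fccs import (
    ConcentrationTriple,
    DetectionCalibration,
    forward_amplitudes,
    invert_amplitudes,
    kd_aggregate,
    kd_point,
)
from .frap import FRAPCurve, fit_recovery
from .models import fit_fcs
from .presets import CALIBRATION, FCCS_CONCENTRATIONS, FCS_PRESETS, FRAP_PRESETS, fcs_preset_params
from .synthetic import generate_model_acf, simulate_frap_curve

__all__ = [
    "default_lag_grid",
    "fcs_recovery_experiment",
    "fccs_kd_experiment",
    "frap_experiment",
]

N_REPLICATES = 20
NOISE_SD_FRACTION = 0.02


def default_lag_grid() -> np.ndarray:
    """Standard fixture lag grid: 0.32 µs to 3.2 s, 250 log-spaced points.

    Matches the span of a hardware multi-tau correlator (sub-µs shortest
    lag, seconds-long acquisition) at a comparable point density.
    """
    return np.logspace(-6.5, 0.5, 250)


def fcs_recovery_experiment(
    preset_name: str,
    seed: int,
    n_replicates: int = N_REPLICATES,
    noise_sd_fraction: float = NOISE_SD_FRACTION,
) -> dict:
    """Generate noisy replicate ACFs from a fixture and fit them back.

    Returns the per-replicate and mean recovered quantities (D_fast, D_slow,
    F_slow) alongside the fixture ground truth.
    """
    preset = FCS_PRESETS[preset_name]
    params = fcs_preset_params(preset, CALIBRATION)
    curves = generate_model_acf(
        preset.spec,
        params,
        default_lag_grid(),
        noise_sd_fraction=noise_sd_fraction,
        n_replicates=n_replicates,
        seed=seed,
        calibration=CALIBRATION,
    )
    d_fast, d_slow, f_slow = [], [], []
    for curve in curves:
        fit = fit_fcs(curve, preset.spec, CALIBRATION, seed=seed)
        d_fast.append(fit.D_fast)
        if preset.spec.n_components == 2:
            d_slow.append(fit.D_slow)
            f_slow.append(fit.F_slow)
    out = {
        "preset": preset_name,
        "model": preset.spec.name,
        "n_replicates": n_replicates,
        "true_D_fast": preset.D_fast,
        "D_fast": d_fast,
        "D_fast_mean": float(np.mean(d_fast)),
        "D_fast_sem": float(np.std(d_fast, ddof=1) / np.sqrt(len(d_fast))),
    }
    if d_slow:
        out.update(
            true_D_slow=preset.D_slow,
            true_F_slow=preset.F_slow,
            D_slow=d_slow,
            D_slow_mean=float(np.mean(d_slow)),
            D_slow_sem=float(np.std(d_slow, ddof=1) / np.sqrt(len(d_slow))),
            F_slow=f_slow,
            F_slow_mean=float(np.mean(f_slow)),
            F_slow_sem=float(np.std(f_slow, ddof=1) / np.sqrt(len(f_slow))),
        )
    return out


def fccs_kd_experiment(n_measurements: int = 23, cv: float = 0.2, seed: int = 0) -> dict:
    """Forward -> invert -> Kd on the ligand-receptor concentration fixture.

    The headline number is the deterministic single-fixture Kd (forward
    amplitudes inverted numerically, then mass action).  A noisy
    ``n_measurements``-sample aggregate around the same truth accompanies it
    with its regression R².
    """
    calib = DetectionCalibration()
    cg, cr, cgr = FCCS_CONCENTRATIONS["wnt3_fzd1"]
    fixture = ConcentrationTriple(cg, cr, cgr)
    amps = forward_amplitudes(fixture, calib)
    recovered = invert_amplitudes(amps, calib)
    kd_fixture = kd_point(recovered)

    rng = np.random.default_rng(seed)
    triples = []
    for _ in range(n_measurements):
        g, r = rng.uniform(10, 100, 2)
        bound = g * r / kd_point(fixture) * rng.lognormal(0.0, cv)
        noisy = ConcentrationTriple(g, r, bound)
        triples.append(invert_amplitudes(forward_amplitudes(noisy, calib), calib))
    agg = kd_aggregate(triples)
    return {
        "amplitudes": {"G_G0": amps.G_G0, "G_R0": amps.G_R0, "G_x0": amps.G_x0},
        "recovered_nM": {"Cg": recovered.Cg, "Cr": recovered.Cr, "Cgr": recovered.Cgr},
        "Kd_nM": kd_fixture,
        "aggregate_Kd_nM": agg.Kd,
        "aggregate_R2": agg.R2,
        "n_measurements": agg.n_measurements,
        "V_eff_fL": calib.V_eff_fL,
    }


def frap_experiment(preset_name: str) -> dict:
    """Simulate a noiseless fixture FRAP curve, fit it, compute D_global."""
    truth = FRAP_PRESETS[preset_name]
    sim = simulate_frap_curve(truth)
    curve = FRAPCurve(sim.time, sim.intensity, sim.n_prebleach, sim.bleach_radius)
    fit = fit_recovery(curve)
    return {
        "preset": preset_name,
        "true_tau_fast_s": truth.tau_fast,
        "true_F_m": truth.F_m,
        "bleach_radius_um": truth.bleach_radius,
        "tau_fast_s": fit.tau_fast,
        "F_m": fit.F_m,
        "D_global_um2_s": fit.D_global,
    }
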