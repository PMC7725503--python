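"""Named study fixtures: measured parameter sets used as ground truth.

Each preset packages a published in vivo measurement of the zebrafish-brain
Wnt3/secEGFP system as a generator ground truth: diffusion coefficients and
component fractions become model parameters on the calibrated observation
volume, so synthetic curves can be generated from them and the analysis
chain can be checked for recovering the same numbers.

All presets share the calibration omega_xy = 0.25 µm (Atto 488 at
400 µm²/s gives tau_d = 39.06 µs) with structure factor K = 5 for 3D fits.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import ConfocalCalibration, FCSModelSpec, D_to_tau
from .synthetic import FRAPGroundTruth

__all__ = [
    "CALIBRATION",
    "FCSPreset",
    "FCS_PRESETS",
    "FRAP_PRESETS",
    "FCCS_CONCENTRATIONS",
    "fcs_preset_params",
]

CALIBRATION = ConfocalCalibration.from_K(omega_xy=0.25, K=5.0, dye_D_ref=400.0)


@dataclass(frozen=True)
class FCSPreset:
    """A measured diffusion scenario usable as generator ground truth."""

    name: str
    spec: FCSModelSpec
    D_fast: float  # µm²/s
    D_slow: float | None = None
    F_slow: float | None = None
    N: float = 10.0
    F_trip: float = 0.15
    tau_trip: float = 1e-5
    G_inf: float = 1.0


FCS_PRESETS = {
    # ligand at cell borders: membrane-bound slow pool + interstitial fast pool
    "wnt3_cell_border": FCSPreset(
        name="wnt3_cell_border",
        spec=FCSModelSpec("2D", 2, True),
        D_fast=27.6,
        D_slow=0.6,
        F_slow=0.6,
    ),
    # ligand free in the brain ventricle; fraction of the slow pool is not
    # published, 0.3 reflects a ventricle dominated by the free species
    "wnt3_ventricle": FCSPreset(
        name="wnt3_ventricle",
        spec=FCSModelSpec("3D", 2, True),
        D_fast=54.6,
        D_slow=4.8,
        F_slow=0.3,
    ),
    # secreted EGFP control, free 3D diffusion in the ventricle
    "secegfp_ventricle": FCSPreset(
        name="secegfp_ventricle",
        spec=FCSModelSpec("3D", 1, True),
        D_fast=87.5,
    ),
    # secreted EGFP control along cell borders
    "secegfp_cell_border": FCSPreset(
        name="secegfp_cell_border",
        spec=FCSModelSpec("2D", 1, True),
        D_fast=57.9,
    ),
    # ligand at cell borders after heparinase disruption of HSPG binding
    "wnt3_heparinase": FCSPreset(
        name="wnt3_heparinase",
        spec=FCSModelSpec("2D", 2, True),
        D_fast=43.4,
        D_slow=0.4,
        F_slow=0.6,
    ),
}


def fcs_preset_params(preset: FCSPreset, calibration: ConfocalCalibration = CALIBRATION) -> dict:
    """Model parameters for a preset on a given calibration.

    Component 2 is the slow component (F2 = F_slow), so fitted F_slow maps
    back directly.
    """
    params = {
        "N": preset.N,
        "tau_d1": D_to_tau(preset.D_fast, calibration.omega_xy),
        "G_inf": preset.G_inf,
    }
    if preset.spec.n_components == 2:
        params["tau_d2"] = D_to_tau(preset.D_slow, calibration.omega_xy)
        params["F2"] = preset.F_slow
    if preset.spec.triplet:
        params["F_trip"] = preset.F_trip
        params["tau_trip"] = preset.tau_trip
    return params


FRAP_PRESETS = {
    # ligand recovery: tau_fast ~5 min, bleach radius consistent with the
    # published D_global of 0.5 µm²/s
    "wnt3": FRAPGroundTruth(
        tau_fast=300.0, tau_slow=3000.0, F_m=0.35, bleach_radius=24.5,
        bleach_depth=0.8, frame_interval=10.0, duration=1800.0,
    ),
    # secreted EGFP control: tau_fast ~30 s, D_global 13 µm²/s
    "secegfp": FRAPGroundTruth(
        tau_fast=30.0, tau_slow=3000.0, F_m=0.8, bleach_radius=39.5,
        bleach_depth=0.8, frame_interval=2.0, duration=1800.0,
    ),
}

# concentration triple consistent with the published ligand-receptor
# dissociation constant: Kd = 40 * 70 / 25 = 112 nM
FCCS_CONCENTRATIONS = {"wnt3_fzd1": (40.0, 70.0, 25.0)}
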