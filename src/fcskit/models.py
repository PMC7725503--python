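"""FCS model family: evaluation, fitting, calibration and model selection.

The model family covers free diffusion through a 3D Gaussian observation
volume, in one or two diffusive components, in 3D or in 2D (membrane-like)
geometry, each multiplied by a triplet-blinking factor and offset by a
long-lag baseline G_inf:

    G_3D,1p(tau) = (1/N) (1 + tau/tau_d)^-1 [1 + (tau/tau_d)/K^2]^-1/2 f_trip(tau) + G_inf
    f_trip(tau)  = 1 + F_trip/(1 - F_trip) exp(-tau/tau_trip)

Two-component variants mix the component terms with fraction F2 of the
second component; 2D variants omit the axial square-root factor.  K is the
structure factor omega_z/omega_xy of the confocal volume and is held fixed
from calibration during sample fits.

Diffusion times convert to diffusion coefficients through the calibrated
radial beam waist: D = omega_xy^2 / (4 tau_d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import lmfit
import numpy as np

__all__ = [
    "ConfocalCalibration",
    "FCSModelSpec",
    "FCSFitResult",
    "FitFailureError",
    "eval_model",
    "triplet_factor",
    "fit_fcs",
    "calibrate",
    "select_model",
    "tau_to_D",
    "D_to_tau",
    "mass_scaling_ratio",
]

# physically motivated fit bounds under the baseline->1 normalization
BOUNDS = {
    "N": (1e-3, 1e4),
    "tau_d": (1e-6, 10.0),
    "tau_trip": (1e-7, 1e-4),
    "F_trip": (0.0, 0.8),
    "F2": (0.0, 1.0),
    "G_inf": (0.5, 1.5),
}


class FitFailureError(RuntimeError):
    """Raised when no fit attempt converges; carries the best attempt."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class ConfocalCalibration:
    """Calibrated confocal observation volume.

    omega_xy and omega_z are the 1/e^2 radial and axial radii (µm); the
    structure factor K = omega_z/omega_xy and the effective volume
    V_eff = pi^(3/2) omega_xy^2 omega_z (fL) are derived on construction.
    """

    omega_xy: float
    omega_z: float
    dye_D_ref: float = 400.0

    def __post_init__(self):
        if self.omega_xy <= 0 or self.omega_z <= 0:
            raise ValueError("beam waists must be positive")

    @property
    def K(self) -> float:
        return self.omega_z / self.omega_xy

    @property
    def V_eff_fL(self) -> float:
        # µm^3 == fL
        return float(np.pi ** 1.5 * self.omega_xy ** 2 * self.omega_z)

    @classmethod
    def from_K(cls, omega_xy: float, K: float, dye_D_ref: float = 400.0):
        return cls(omega_xy=omega_xy, omega_z=K * omega_xy, dye_D_ref=dye_D_ref)


@dataclass(frozen=True)
class FCSModelSpec:
    """One member of the model family: dimensionality x components x triplet."""

    dimensionality: str = "3D"  # "2D" or "3D"
    n_components: int = 1  # 1 or 2
    triplet: bool = True

    def __post_init__(self):
        if self.dimensionality not in ("2D", "3D"):
            raise ValueError("dimensionality must be '2D' or '3D'")
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")

    @property
    def name(self) -> str:
        t = "1t" if self.triplet else "0t"
        return f"{self.dimensionality.lower()}{self.n_components}p{t}"

    @property
    def n_free_params(self) -> int:
        n = 3  # N, tau_d1, G_inf
        if self.n_components == 2:
            n += 2  # tau_d2, F2
        if self.triplet:
            n += 2  # F_trip, tau_trip
        return n

    @classmethod
    def parse(cls, name: str) -> "FCSModelSpec":
        """Parse names like '2d2p1t', '3D1P0T'."""
        s = name.lower()
        try:
            dim = {"2d": "2D", "3d": "3D"}[s[:2]]
            ncomp = int(s[2])
            trip = s[4] == "1"
        except (KeyError, IndexError, ValueError):
            raise ValueError(f"cannot parse model spec {name!r}") from None
        return cls(dimensionality=dim, n_components=ncomp, triplet=trip)


def triplet_factor(tau, F_trip: float, tau_trip: float):
    """Triplet-blinking factor: 1 + F/(1-F) exp(-tau/tau_trip)."""
    tau = np.asarray(tau, dtype=float)
    if F_trip == 0:
        return np.ones_like(tau)
    return 1.0 + F_trip / (1.0 - F_trip) * np.exp(-tau / tau_trip)


def _component(tau, tau_d, K, dimensionality):
    g = 1.0 / (1.0 + tau / tau_d)
    if dimensionality == "3D":
        g = g / np.sqrt(1.0 + tau / (K * K * tau_d))
    return g


def eval_model(
    spec: FCSModelSpec,
    params: dict,
    calibration: Optional[ConfocalCalibration] = None,
    tau=None,
):
    """Evaluate G(tau) for a model spec.

    ``params`` keys: N, tau_d1 (and tau_d2, F2 for two components), F_trip,
    tau_trip, G_inf.  For 3D specs the structure factor comes from
    ``calibration`` unless a ``K`` key is supplied directly (used while
    calibrating, where K itself is fitted).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("lag times must be strictly positive")
    K = params.get("K")
    if spec.dimensionality == "3D":
        if K is None:
            if calibration is None:
                raise ValueError("3D models need a calibration or explicit K")
            K = calibration.K
        if K <= 0:
            raise ValueError("structure factor K must be positive for 3D models")
    N = params["N"]
    g = _component(tau, params["tau_d1"], K, spec.dimensionality)
    if spec.n_components == 2:
        F2 = params["F2"]
        g2 = _component(tau, params["tau_d2"], K, spec.dimensionality)
        g = (1.0 - F2) * g + F2 * g2
    if spec.triplet:
        g = g * triplet_factor(tau, params.get("F_trip", 0.0), params.get("tau_trip", 1e-6))
    return g / N + params.get("G_inf", 0.0)


@dataclass
class FCSFitResult:
    """Fitted FCS parameters plus derived diffusion coefficients.

    Components are relabeled after fitting so that ``tau_fast <= tau_slow``;
    ``F_slow`` is the fraction of the slower component, and ``D_fast``/
    ``D_slow`` derive from the calibrated beam waist.
    """

    spec: FCSModelSpec
    N: float
    tau_d1: float
    G_inf: float
    tau_d2: Optional[float] = None
    F2: Optional[float] = None
    F_trip: float = 0.0
    tau_trip: Optional[float] = None
    K: Optional[float] = None
    omega_xy: Optional[float] = None
    redchi: float = np.nan
    bic: float = np.nan
    success: bool = True
    flags: list = field(default_factory=list)
    stderr: dict = field(default_factory=dict)

    @property
    def tau_fast(self) -> float:
        if self.spec.n_components == 1:
            return self.tau_d1
        return min(self.tau_d1, self.tau_d2)

    @property
    def tau_slow(self) -> Optional[float]:
        if self.spec.n_components == 1:
            return None
        return max(self.tau_d1, self.tau_d2)

    @property
    def F_slow(self) -> Optional[float]:
        if self.spec.n_components == 1:
            return None
        return self.F2 if self.tau_d2 >= self.tau_d1 else 1.0 - self.F2

    @property
    def D_fast(self) -> Optional[float]:
        if self.omega_xy is None:
            return None
        return tau_to_D(self.tau_fast, self.omega_xy)

    @property
    def D_slow(self) -> Optional[float]:
        if self.omega_xy is None or self.tau_slow is None:
            return None
        return tau_to_D(self.tau_slow, self.omega_xy)

    @property
    def D1(self) -> Optional[float]:
        return None if self.omega_xy is None else tau_to_D(self.tau_d1, self.omega_xy)

    @property
    def D2(self) -> Optional[float]:
        if self.omega_xy is None or self.tau_d2 is None:
            return None
        return tau_to_D(self.tau_d2, self.omega_xy)

    def params_dict(self) -> dict:
        d = {"N": self.N, "tau_d1": self.tau_d1, "G_inf": self.G_inf}
        if self.spec.n_components == 2:
            d.update(tau_d2=self.tau_d2, F2=self.F2)
        if self.spec.triplet:
            d.update(F_trip=self.F_trip, tau_trip=self.tau_trip)
        if self.K is not None:
            d["K"] = self.K
        return d

    def to_dict(self) -> dict:
        out = {
            "model": self.spec.name,
            **self.params_dict(),
            "tau_fast_s": self.tau_fast,
            "tau_slow_s": self.tau_slow,
            "F_slow": self.F_slow,
            "D_fast_um2_s": self.D_fast,
            "D_slow_um2_s": self.D_slow,
            "redchi": self.redchi,
            "bic": self.bic,
            "success": self.success,
            "flags": list(self.flags),
            "stderr": dict(self.stderr),
        }
        return out


def _make_params(spec: FCSModelSpec, init: dict, fit_K: bool = False, K: float = 5.0):
    p = lmfit.Parameters()
    p.add("N", value=init["N"], min=BOUNDS["N"][0], max=BOUNDS["N"][1])
    p.add("tau_d1", value=init["tau_d1"], min=BOUNDS["tau_d"][0], max=BOUNDS["tau_d"][1])
    if spec.n_components == 2:
        p.add("tau_d2", value=init["tau_d2"], min=BOUNDS["tau_d"][0], max=BOUNDS["tau_d"][1])
        p.add("F2", value=init.get("F2", 0.5), min=BOUNDS["F2"][0], max=BOUNDS["F2"][1])
    if spec.triplet:
        p.add("F_trip", value=init.get("F_trip", 0.1), min=BOUNDS["F_trip"][0],
              max=BOUNDS["F_trip"][1])
        p.add("tau_trip", value=init.get("tau_trip", 5e-6), min=BOUNDS["tau_trip"][0],
              max=BOUNDS["tau_trip"][1])
    p.add("G_inf", value=init.get("G_inf", 1.0), min=BOUNDS["G_inf"][0],
          max=BOUNDS["G_inf"][1])
    if spec.dimensionality == "3D":
        p.add("K", value=K, min=0.5, max=50.0, vary=fit_K)
    return p


def _half_amplitude_lag(lags, G):
    """Lag at which the offset-subtracted curve decays to half amplitude."""
    baseline = np.median(G[-max(3, len(G) // 10):])
    amp = G[0] - baseline
    if amp <= 0:
        return lags[len(lags) // 2]
    target = baseline + amp / 2.0
    below = np.nonzero(G <= target)[0]
    return lags[below[0]] if below.size else lags[-1]


def fit_fcs(
    curve,
    spec: FCSModelSpec,
    calibration: Optional[ConfocalCalibration] = None,
    weights: Optional[np.ndarray] = None,
    n_restarts: int = 5,
    seed: int = 0,
    _fit_K: bool = False,
) -> FCSFitResult:
    """Weighted least-squares fit of a correlation curve.

    Weights default to 1/sd^2 when the curve carries per-lag SDs, else
    uniform.  Initialization places tau_d at the half-amplitude lag (the two
    component starts bracket it by a factor 10 each way) and runs
    ``n_restarts`` jittered restarts, keeping the best chi-square.  K is held
    fixed at the calibration value for 3D specs unless calibrating.
    """
    lags = curve.lags
    G = curve.G
    n_free = spec.n_free_params + (1 if _fit_K else 0)
    if lags.size < 3 * n_free:
        raise ValueError(
            f"curve has {lags.size} points; need >= {3 * n_free} for {spec.name}"
        )
    if weights is None:
        if curve.sd is not None and np.all(curve.sd > 0):
            weights = 1.0 / curve.sd
        else:
            weights = np.ones_like(G)
    weights = np.asarray(weights, dtype=float)

    K = calibration.K if (calibration is not None and spec.dimensionality == "3D") else 5.0
    baseline = np.median(G[-max(3, len(G) // 10):])
    amp = max(G[0] - baseline, 1e-6)
    tau_half = _half_amplitude_lag(lags, G)
    init = {
        "N": min(max(1.0 / amp, BOUNDS["N"][0] * 1.01), BOUNDS["N"][1] * 0.99),
        "tau_d1": tau_half,
        "tau_d2": min(tau_half * 10, BOUNDS["tau_d"][1] * 0.5),
        "F2": 0.5,
        "G_inf": float(np.clip(baseline, *BOUNDS["G_inf"])),
    }
    if spec.n_components == 2:
        init["tau_d1"] = max(tau_half / 10, BOUNDS["tau_d"][0] * 2)

    def resid(p):
        model = eval_model(spec, {k: p[k].value for k in p}, calibration, lags)
        return (model - G) * weights

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(n_restarts):
        trial_init = dict(init)
        if trial > 0:
            for key in ("tau_d1", "tau_d2"):
                if key in trial_init:
                    trial_init[key] *= float(np.exp(rng.normal(0, 1.0)))
                    trial_init[key] = float(
                        np.clip(trial_init[key], BOUNDS["tau_d"][0] * 2, BOUNDS["tau_d"][1] * 0.5)
                    )
            trial_init["F2"] = float(rng.uniform(0.2, 0.8))
        params = _make_params(spec, trial_init, fit_K=_fit_K, K=K)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = lmfit.minimize(resid, params, method="leastsq")
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res

    if best is None:
        raise FitFailureError(f"no converged fit for {spec.name}", best=None)

    p = best.params
    flags = []
    for name in p:
        if not p[name].vary:
            continue
        lo, hi = p[name].min, p[name].max
        span = hi - lo
        if span > 0 and (p[name].value - lo < 1e-3 * span or hi - p[name].value < 1e-3 * span):
            flags.append(f"{name}_at_bound")

    result = FCSFitResult(
        spec=spec,
        N=p["N"].value,
        tau_d1=p["tau_d1"].value,
        tau_d2=p["tau_d2"].value if spec.n_components == 2 else None,
        F2=p["F2"].value if spec.n_components == 2 else None,
        F_trip=p["F_trip"].value if spec.triplet else 0.0,
        tau_trip=p["tau_trip"].value if spec.triplet else None,
        G_inf=p["G_inf"].value,
        K=p["K"].value if spec.dimensionality == "3D" else None,
        omega_xy=calibration.omega_xy if calibration is not None else None,
        redchi=best.redchi,
        bic=_bic(best),
        success=True,
        flags=flags,
        stderr={n: (p[n].stderr if p[n].stderr is not None else np.nan)
                for n in p if p[n].vary},
    )
    return result


def _bic(res) -> float:
    n = res.ndata
    k = res.nvarys
    chisqr = max(res.chisqr, 1e-300)
    return float(n * np.log(chisqr / n) + k * np.log(n))


def calibrate(dye_curve, dye_D_ref: float = 400.0, seed: int = 0) -> ConfocalCalibration:
    """Calibrate the observation volume from a reference-dye autocorrelation.

    Fits the 3D one-component triplet model with the structure factor K free,
    then converts the fitted diffusion time through the dye's known diffusion
    coefficient (Atto 488: 400 µm²/s at room temperature):
    omega_xy = sqrt(4 D_ref tau_d), omega_z = K omega_xy.
    """
    if dye_D_ref <= 0:
        raise ValueError("dye_D_ref must be positive")
    spec = FCSModelSpec("3D", 1, True)
    fit = fit_fcs(dye_curve, spec, calibration=None, seed=seed, _fit_K=True)
    K = fit.K
    if not (3.0 <= K <= 10.0):
        warnings.warn(
            f"fitted structure factor K={K:.2f} outside the typical confocal "
            "range [3, 10]; check the calibration measurement",
            stacklevel=2,
        )
    omega_xy = float(np.sqrt(4.0 * dye_D_ref * fit.tau_d1))
    return ConfocalCalibration(omega_xy=omega_xy, omega_z=K * omega_xy, dye_D_ref=dye_D_ref)


def select_model(
    curve,
    candidates: Sequence[FCSModelSpec],
    calibration: Optional[ConfocalCalibration] = None,
    weights: Optional[np.ndarray] = None,
    seed: int = 0,
):
    """Fit every candidate spec and pick the best by BIC.

    Candidates within 2 BIC units of the minimum are treated as tied and the
    tie is broken toward the fewest free parameters (nested-model parsimony).
    Returns ``(best_spec, table)`` where the table lists per-candidate scores.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    rows = []
    fits = {}
    for spec in candidates:
        try:
            fit = fit_fcs(curve, spec, calibration, weights=weights, seed=seed)
            rows.append({"model": spec.name, "bic": fit.bic, "redchi": fit.redchi,
                         "n_params": spec.n_free_params, "success": True})
            fits[spec.name] = fit
        except (FitFailureError, ValueError) as exc:
            rows.append({"model": spec.name, "bic": np.inf, "redchi": np.inf,
                         "n_params": spec.n_free_params, "success": False,
                         "error": str(exc)})
    if not fits:
        raise FitFailureError("all candidate models failed to fit")
    best_bic = min(r["bic"] for r in rows)
    tied = [r for r in rows if r["bic"] - best_bic < 2.0]
    winner = min(tied, key=lambda r: (r["n_params"], r["bic"]))
    best_spec = next(s for s in candidates if s.name == winner["model"])
    return best_spec, rows


def tau_to_D(tau_d: float, omega_xy: float) -> float:
    """Diffusion time -> diffusion coefficient, D = omega_xy^2 / (4 tau_d)."""
    if tau_d <= 0 or omega_xy <= 0:
        raise ValueError("tau_d and omega_xy must be positive")
    return omega_xy ** 2 / (4.0 * tau_d)


def D_to_tau(D: float, omega_xy: float) -> float:
    """Diffusion coefficient -> residence time in the observation area."""
    if D <= 0 or omega_xy <= 0:
        raise ValueError("D and omega_xy must be positive")
    return omega_xy ** 2 / (4.0 * D)


def mass_scaling_ratio(m1: float, m2: float) -> float:
    """Expected D1/D2 for free diffusion of globular species of mass m1, m2.

    Stokes-Einstein with radius ~ mass^(1/3) gives D inversely proportional
    to the cube root of the mass, so D1/D2 = (m2/m1)^(1/3).
    """
    if m1 <= 0 or m2 <= 0:
        raise ValueError("masses must be positive")
    return float((m2 / m1) ** (1.0 / 3.0))
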