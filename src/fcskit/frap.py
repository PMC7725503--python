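"""FRAP normalization, double-exponential recovery fitting and D_global.

A bleached region of radius r recovers with two exponential time constants:
a fast term attributed to diffusive exchange with the unbleached
surroundings and a slow term attributed to fluorophore production and
maturation.  The apparent ensemble diffusion coefficient uses the fast term
only:

    D_global = r^2 / (4 tau_fast)

This is an apparent estimate — fluorophores are not homogeneously
distributed and bleaching is assumed instantaneous — but it makes local
(fluctuation-based) and global (recovery-based) mobility directly
comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np

__all__ = [
    "FRAPCurve",
    "FRAPFit",
    "NormalizationError",
    "normalize_frap",
    "fit_recovery",
    "d_global",
]


class NormalizationError(ValueError):
    """Reference signal non-positive after background subtraction."""


@dataclass
class FRAPCurve:
    """Normalized FRAP time series; t = 0 is the end of the bleach.

    Pre-bleach frames (negative times) average to 1 by construction.
    """

    time: np.ndarray
    intensity: np.ndarray
    n_prebleach: int
    bleach_radius: Optional[float] = None  # µm

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must match in length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.n_prebleach < 0 or self.n_prebleach > self.time.size:
            raise ValueError("invalid n_prebleach")

    @property
    def post_time(self) -> np.ndarray:
        return self.time[self.n_prebleach:]

    @property
    def post_intensity(self) -> np.ndarray:
        return self.intensity[self.n_prebleach:]


@dataclass
class FRAPFit:
    """Double-exponential recovery fit.

    Components are ordered so tau_fast < tau_slow.  The mobile fraction is
    F_m = (I_plateau - I0) / (1 - I0) with I_plateau = I0 + A_fast + A_slow:
    the recovered share of what the bleach removed.
    """

    tau_fast: float
    tau_slow: float
    amplitude_fast: float
    amplitude_slow: float
    I0: float
    F_m: float
    D_global: Optional[float] = None  # µm²/s, from tau_fast and bleach radius
    redchi: float = np.nan
    success: bool = True
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tau_fast_s": self.tau_fast,
            "tau_slow_s": self.tau_slow,
            "amplitude_fast": self.amplitude_fast,
            "amplitude_slow": self.amplitude_slow,
            "I0": self.I0,
            "F_m": self.F_m,
            "D_global_um2_s": self.D_global,
            "redchi": self.redchi,
            "success": self.success,
            "flags": list(self.flags),
        }


def normalize_frap(
    time: np.ndarray,
    roi: np.ndarray,
    reference: np.ndarray,
    background: np.ndarray | float,
    n_prebleach: int,
    bleach_radius: Optional[float] = None,
) -> FRAPCurve:
    """Double normalization of a raw FRAP ROI trace.

    Background-subtracts both the ROI and the reference region, divides the
    ROI by the reference to cancel acquisition photobleaching, and scales by
    the pre-bleach mean of the same ratio:

        I_norm(t) = [(ROI - BG) / (REF - BG)] / <(ROI - BG)/(REF - BG)>_pre

    The reference region sits outside the bleached ROI (corrects for
    monitoring bleach); the background region sits outside the sample.
    """
    time = np.asarray(time, dtype=float)
    roi = np.asarray(roi, dtype=float)
    reference = np.asarray(reference, dtype=float)
    background = np.broadcast_to(np.asarray(background, dtype=float), roi.shape)
    if n_prebleach < 3:
        raise ValueError("need >= 3 pre-bleach frames")
    ref_corr = reference - background
    if np.any(ref_corr <= 0):
        raise NormalizationError("reference - background <= 0 at some frame")
    ratio = (roi - background) / ref_corr
    pre_mean = ratio[:n_prebleach].mean()
    if pre_mean <= 0:
        raise NormalizationError("pre-bleach ratio mean is non-positive")
    t0 = time[n_prebleach]
    return FRAPCurve(
        time=time - t0,
        intensity=ratio / pre_mean,
        n_prebleach=n_prebleach,
        bleach_radius=bleach_radius,
    )


def fit_recovery(curve: FRAPCurve, tau_fast_guess: Optional[float] = None) -> FRAPFit:
    """Fit the post-bleach recovery with a double exponential.

        I(t) = I0 + A_f (1 - e^(-t/tau_fast)) + A_s (1 - e^(-t/tau_slow))

    Falls back to a single exponential (flagged) if the double-exponential
    fit does not converge.  Raises if the post-bleach window is shorter than
    3x the initial fast-time guess — the fast constant is then unconstrained.
    """
    t = curve.post_time
    y = curve.post_intensity
    if t.size < 8:
        raise ValueError("too few post-bleach frames to fit")
    span = t[-1] - t[0]
    if tau_fast_guess is None:
        # time to reach half of the apparent recovery
        i0 = y[:3].mean()
        plateau = y[-max(3, y.size // 10):].mean()
        half = i0 + 0.5 * (plateau - i0)
        above = np.nonzero(y >= half)[0]
        tau_fast_guess = t[above[0]] if above.size and t[above[0]] > 0 else span / 10.0
    if span < 3.0 * tau_fast_guess:
        raise ValueError(
            f"post-bleach duration {span:.3g} s < 3x the initial fast-time "
            f"guess {tau_fast_guess:.3g} s; recovery is unconstrained"
        )

    i0_guess = float(y[:3].mean())
    plateau = float(y[-max(3, y.size // 10):].mean())
    amp = max(plateau - i0_guess, 1e-6)

    params = lmfit.Parameters()
    params.add("I0", value=i0_guess, min=-0.5, max=1.5)
    params.add("A_f", value=0.7 * amp, min=0.0, max=2.0)
    params.add("A_s", value=0.3 * amp, min=0.0, max=2.0)
    params.add("tau_f", value=tau_fast_guess, min=span * 1e-5, max=span * 10)
    params.add("tau_s", value=min(10 * tau_fast_guess, span * 5), min=span * 1e-5,
               max=span * 100)

    def model(p, tt):
        return (
            p["I0"]
            + p["A_f"] * (1.0 - np.exp(-tt / p["tau_f"]))
            + p["A_s"] * (1.0 - np.exp(-tt / p["tau_s"]))
        )

    def resid(p):
        return model(p, t) - y

    flags = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = lmfit.minimize(resid, params, method="leastsq")
    if not res.success:
        # single-exponential fallback
        sp = lmfit.Parameters()
        sp.add("I0", value=i0_guess, min=-0.5, max=1.5)
        sp.add("A_f", value=amp, min=0.0, max=2.0)
        sp.add("tau_f", value=tau_fast_guess, min=span * 1e-5, max=span * 10)

        def resid1(p):
            return p["I0"] + p["A_f"] * (1.0 - np.exp(-t / p["tau_f"])) - y

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lmfit.minimize(resid1, sp, method="leastsq")
        flags.append("single_exponential_fallback")
        p = res.params
        tau_f, tau_s = p["tau_f"].value, np.inf
        a_f, a_s = p["A_f"].value, 0.0
    else:
        p = res.params
        tau_f, tau_s = p["tau_f"].value, p["tau_s"].value
        a_f, a_s = p["A_f"].value, p["A_s"].value
        if tau_f > tau_s:  # order components
            tau_f, tau_s = tau_s, tau_f
            a_f, a_s = a_s, a_f

    i0 = p["I0"].value
    plateau_fit = i0 + a_f + a_s
    f_m = (plateau_fit - i0) / (1.0 - i0) if i0 < 1.0 else np.nan
    f_m = float(np.clip(f_m, 0.0, 1.0)) if np.isfinite(f_m) else f_m
    dg = None
    if curve.bleach_radius is not None and tau_f > 0:
        dg = d_global(tau_f, curve.bleach_radius)
    return FRAPFit(
        tau_fast=tau_f,
        tau_slow=tau_s,
        amplitude_fast=a_f,
        amplitude_slow=a_s,
        I0=i0,
        F_m=f_m,
        D_global=dg,
        redchi=res.redchi,
        success=res.success,
        flags=flags,
    )


def d_global(tau_fast: float, r: float) -> float:
    """Apparent ensemble diffusion coefficient: D = r^2 / (4 tau_fast).

    r is the nominal radius of the circular bleach region (µm), tau_fast the
    fitted fast recovery constant (s).
    """
    if tau_fast <= 0 or r <= 0:
        raise ValueError("tau_fast and r must be positive")
    return r * r / (4.0 * tau_fast)
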