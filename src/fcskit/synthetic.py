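"""Synthetic-data generators with known ground truth.

Four generators cover the pipeline's inputs:

* Brownian-dynamics photon traces: point particles diffuse in a periodic box
  and are observed through a 3D Gaussian detection profile; per-bin expected
  counts are realized as Poisson draws, with optional two-state triplet
  blinking and detector background.  Identical trajectories feed every
  detection channel, so perfectly co-diffusing two-color species are
  available for cross-correlation tests.
* Model autocorrelation curves: exact model values on a lag grid plus
  lag-independent Gaussian noise scaled to the curve amplitude.
* FRAP recovery curves: double-exponential recovery with an immobile
  fraction and pre-bleach frames at unit intensity.
* Dual-channel 3D stacks: thin shell ("membrane") structures, a controlled
  fraction carrying signal in both channels, blurred by a Gaussian PSF and
  corrupted with Poisson noise, with voxel-level ground-truth labels.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .correlate import IntensityTrace, CorrelationCurve
from .models import FCSModelSpec, ConfocalCalibration, eval_model

__all__ = [
    "FCSSimConfig",
    "FRAPGroundTruth",
    "ColocGroundTruth",
    "FRAPCurveData",
    "simulate_fcs_traces",
    "generate_model_acf",
    "simulate_frap_curve",
    "simulate_stack_pair",
]

logger = logging.getLogger(__name__)

LABEL_BACKGROUND = 0
LABEL_COLOC = 1
LABEL_GREEN_ONLY = 2


@dataclass(frozen=True)
class FCSSimConfig:
    """Physical scenario for a Brownian-dynamics photon-trace simulation.

    ``brightness`` is indexed ``[species][channel]`` in mean detected counts
    per particle per second at beam center (Hz).  The box is periodic and
    must be at least 10 radial beam waists wide so that re-entry artifacts
    stay negligible.
    """

    box_side: float = 3.0  # µm
    n_particles: Sequence[int] = (20,)
    D: Sequence[float] = (400.0,)  # µm²/s per species
    brightness: Sequence[Sequence[float]] = ((20000.0,),)  # Hz, [species][channel]
    triplet_fraction: float = 0.0
    triplet_time: float = 5e-6  # s
    background: Sequence[float] = (0.0,)  # Hz per channel
    omega_xy: float = 0.25  # µm
    omega_z: float = 1.25  # µm
    bin_time: float = 2e-6  # s
    duration: float = 0.2  # s
    seed: Optional[int] = None

    def __post_init__(self):
        if self.bin_time <= 0 or self.duration <= 0:
            raise ValueError("bin_time and duration must be positive")
        if self.box_side < 10 * self.omega_xy:
            raise ValueError("box_side must be >= 10 * omega_xy")
        if not (0 <= self.triplet_fraction < 1):
            raise ValueError("triplet_fraction must be in [0, 1)")
        n_bins = int(round(self.duration / self.bin_time))
        if n_bins < 10_000:
            raise ValueError("duration/bin_time must give >= 10^4 bins")
        if len(self.n_particles) != len(self.D) or len(self.D) != len(self.brightness):
            raise ValueError("n_particles, D and brightness must align per species")
        n_chan = len(self.background)
        for b in self.brightness:
            if len(b) != n_chan:
                raise ValueError("brightness rows must match number of channels")
            if any(x < 0 for x in b):
                raise ValueError("brightness must be non-negative")
        if any(x < 0 for x in self.background) or any(d < 0 for d in self.D):
            raise ValueError("rates must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_time))

    @property
    def n_channels(self) -> int:
        return len(self.background)


def _telegraph(rng, n_steps, n_particles, dt, fraction, relax_time):
    """Two-state on/off blinking: stationary dark fraction and relaxation time.

    Dark fraction F and relaxation time tau give rates k_dark = F/tau,
    k_bright = (1-F)/tau; states evolve as a discrete-time Markov chain.
    Returns a boolean (n_steps, n_particles) "emitting" array.
    """
    k_total = 1.0 / relax_time
    p_to_dark = fraction * k_total * dt
    p_to_bright = (1.0 - fraction) * k_total * dt
    if p_to_dark > 0.5 or p_to_bright > 0.5:
        raise ValueError("bin_time too coarse for the requested triplet_time")
    state = rng.random(n_particles) >= fraction  # True = emitting, stationary start
    u = rng.random((n_steps, n_particles))
    out = np.empty((n_steps, n_particles), dtype=bool)
    for i in range(n_steps):
        flip_dark = state & (u[i] < p_to_dark)
        flip_bright = (~state) & (u[i] < p_to_bright)
        state = np.where(flip_dark, False, np.where(flip_bright, True, state))
        out[i] = state
    return out


def simulate_fcs_traces(config: FCSSimConfig):
    """Brownian-dynamics photon-count traces through a Gaussian volume.

    Returns ``(traces, truth)``: one :class:`IntensityTrace` per channel and
    a ground-truth dict echoing the configuration plus derived quantities
    (expected mean count rate per channel, diffusion times).
    """
    seed = config.seed
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2 ** 31))
        logger.warning("no seed supplied; drew seed=%d", seed)
    rng = np.random.default_rng(seed)

    n_bins = config.n_bins
    dt = config.bin_time
    L = config.box_side
    half = L / 2.0
    n_chan = config.n_channels
    expected = np.zeros((n_bins, n_chan))

    chunk = 40_000
    for sp, (n_p, D, bright) in enumerate(
        zip(config.n_particles, config.D, config.brightness)
    ):
        if n_p == 0:
            continue
        sigma = np.sqrt(2.0 * D * dt)
        pos = rng.uniform(-half, half, size=(n_p, 3))
        if config.triplet_fraction > 0:
            blink_full = _telegraph(
                rng, n_bins, n_p, dt, config.triplet_fraction, config.triplet_time
            )
        for start in range(0, n_bins, chunk):
            stop = min(start + chunk, n_bins)
            steps = rng.normal(0.0, sigma, size=(stop - start, n_p, 3))
            traj = pos[None, :, :] + np.cumsum(steps, axis=0)
            pos = traj[-1]
            # wrap into the centered periodic box
            traj = (traj + half) % L - half
            pos = (pos + half) % L - half
            w = np.exp(
                -2.0 * (traj[..., 0] ** 2 + traj[..., 1] ** 2) / config.omega_xy ** 2
                - 2.0 * traj[..., 2] ** 2 / config.omega_z ** 2
            )
            if config.triplet_fraction > 0:
                w = w * blink_full[start:stop]
            for ch in range(n_chan):
                if bright[ch] > 0:
                    expected[start:stop, ch] += bright[ch] * dt * w.sum(axis=1)

    labels = ["G", "R"][:n_chan] if n_chan <= 2 else [f"C{i}" for i in range(n_chan)]
    traces = []
    for ch in range(n_chan):
        lam = expected[:, ch] + config.background[ch] * dt
        counts = rng.poisson(lam)
        traces.append(IntensityTrace(bin_time=dt, counts=counts, channel=labels[ch]))

    truth = {
        "config": {**asdict(config), "seed": seed},
        "tau_d_s": [
            config.omega_xy ** 2 / (4.0 * D) if D > 0 else np.inf for D in config.D
        ],
        "expected_rate_hz": [
            float(expected[:, ch].mean() / dt + config.background[ch])
            for ch in range(n_chan)
        ],
    }
    return traces, truth


def generate_model_acf(
    spec: FCSModelSpec,
    params: dict,
    lag_grid: np.ndarray,
    noise_sd_fraction: float = 0.0,
    n_replicates: int = 1,
    seed: Optional[int] = None,
    calibration: Optional[ConfocalCalibration] = None,
) -> list[CorrelationCurve]:
    """Forward-evaluate a model ACF on a lag grid, with optional noise.

    Noise is zero-mean Gaussian, lag-independent, with standard deviation
    ``noise_sd_fraction * (G(smallest lag) - G_inf)`` — a fixed fraction of
    the fluctuation amplitude.  ``noise_sd_fraction = 0`` returns the exact
    model; each replicate then carries a per-lag SD equal to the noise SD so
    downstream fits are correctly weighted.
    """
    lag_grid = np.asarray(lag_grid, dtype=float)
    if np.any(lag_grid <= 0):
        raise ValueError("lag grid must be strictly positive")
    if np.any(np.diff(lag_grid) <= 0):
        raise ValueError("lag grid must be strictly increasing")
    exact = eval_model(spec, params, calibration, lag_grid)
    amp = exact[0] - params.get("G_inf", 0.0)
    sd = noise_sd_fraction * amp
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_replicates):
        if sd > 0:
            g = exact + rng.normal(0.0, sd, size=lag_grid.shape)
            curve = CorrelationCurve(lag_grid, g, sd=np.full_like(g, sd))
        else:
            curve = CorrelationCurve(lag_grid, exact.copy())
        curve.meta.update(model=spec.name, noise_sd=float(sd), true_params=dict(params))
        curves.append(curve)
    return curves


@dataclass(frozen=True)
class FRAPGroundTruth:
    """Ground truth for a double-exponential FRAP recovery simulation.

    The recovery has a fast and a slow component (amplitude split
    ``a_fast`` of the mobile recovery on the fast term) and a mobile
    fraction ``F_m``; the immobile remainder never recovers.
    """

    tau_fast: float = 300.0  # s
    tau_slow: float = 3000.0  # s
    F_m: float = 0.35
    bleach_radius: float = 24.5  # µm
    bleach_depth: float = 0.8  # fraction of pre-bleach intensity removed
    noise_sd: float = 0.0  # fraction of pre-bleach intensity
    n_prebleach: int = 5
    frame_interval: float = 10.0  # s
    duration: float = 1800.0  # s post-bleach
    a_fast: float = 0.8
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.tau_fast < self.tau_slow:
            raise ValueError("tau_fast must be < tau_slow")
        if not (0 <= self.F_m <= 1):
            raise ValueError("F_m must be in [0, 1]")
        if not (0 < self.bleach_depth <= 1):
            raise ValueError("bleach_depth must be in (0, 1]")
        if not (0 <= self.a_fast <= 1):
            raise ValueError("a_fast must be in [0, 1]")


@dataclass
class FRAPCurveData:
    """Simulated FRAP observation: times (0 at bleach end) and intensities."""

    time: np.ndarray
    intensity: np.ndarray
    n_prebleach: int
    bleach_radius: float
    truth: Optional[FRAPGroundTruth] = None


def simulate_frap_curve(truth: FRAPGroundTruth) -> FRAPCurveData:
    """Simulate a normalized FRAP recovery curve.

    Pre-bleach frames sit at 1; the post-bleach intensity is

        I(t) = (1 - depth) + depth * F_m * [a_f (1 - e^(-t/tau_fast))
                                            + (1 - a_f)(1 - e^(-t/tau_slow))]

    plus Gaussian noise of SD ``noise_sd`` (fraction of pre-bleach level).
    The long-time plateau is 1 - depth*(1 - F_m).
    """
    if truth.duration < 5 * truth.tau_fast:
        logger.warning(
            "post-bleach duration %.3g s < 5 * tau_fast (%.3g s); fit may be unstable",
            truth.duration,
            truth.tau_fast,
        )
    dt = truth.frame_interval
    t_pre = -dt * np.arange(truth.n_prebleach, 0, -1)
    n_post = int(np.floor(truth.duration / dt)) + 1
    t_post = dt * np.arange(n_post)
    d = truth.bleach_depth
    recov = truth.a_fast * (1.0 - np.exp(-t_post / truth.tau_fast)) + (
        1.0 - truth.a_fast
    ) * (1.0 - np.exp(-t_post / truth.tau_slow))
    i_post = (1.0 - d) + d * truth.F_m * recov
    intensity = np.concatenate([np.ones_like(t_pre), i_post])
    time = np.concatenate([t_pre, t_post])
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        intensity = intensity + rng.normal(0.0, truth.noise_sd, size=intensity.shape)
    return FRAPCurveData(
        time=time,
        intensity=intensity,
        n_prebleach=truth.n_prebleach,
        bleach_radius=truth.bleach_radius,
        truth=truth,
    )


@dataclass(frozen=True)
class ColocGroundTruth:
    """Ground truth for a dual-channel 3D stack with known colocalization."""

    volume_dims: tuple = (16, 64, 64)  # voxels (z, y, x)
    voxel_size: tuple = (0.5, 0.2, 0.2)  # µm per axis
    n_structures: int = 12
    colocalized_fraction: float = 0.5
    psf_sigma: float = 1.0  # voxels
    photon_scale: float = 100.0  # counts
    background: float = 2.0  # counts
    seed: Optional[int] = None

    def __post_init__(self):
        if not (0 <= self.colocalized_fraction <= 1):
            raise ValueError("colocalized_fraction must be in [0, 1]")
        if any(d < 8 for d in self.volume_dims):
            raise ValueError("each volume dimension must be >= 8 voxels")
        if self.n_structures < 1:
            raise ValueError("need at least one structure")


def _shell_mask(dims, center, radius, thickness=1.2):
    zz, yy, xx = np.ogrid[: dims[0], : dims[1], : dims[2]]
    r = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    return np.abs(r - radius) <= thickness / 2.0 + 0.5


def simulate_stack_pair(truth: ColocGroundTruth):
    """Simulate a registered dual-channel 3D stack with labeled structures.

    Thin spherical shells stand in for membrane-bound structures.  A fraction
    ``colocalized_fraction`` of them emits in both channels, the rest in the
    green channel only.  Both channels are blurred by a Gaussian PSF and
    corrupted with Poisson noise on top of a constant background.

    Returns ``(green, red, labels)`` where ``labels`` marks each voxel as
    background (0), colocalized (1) or green-only (2).  Labels are defined on
    the noiseless PSF-blurred signal support — a voxel belongs to a structure
    when the structure's expected photon signal exceeds the background's
    shot-noise band (background + 4 sqrt(background)) — since a one-voxel
    shell is not commensurable with a PSF-widened detection mask, and voxels
    whose signal drowns in background shot noise are invisible to any
    segmenter.
    """
    rng = np.random.default_rng(truth.seed)
    dims = truth.volume_dims
    n_coloc = int(round(truth.colocalized_fraction * truth.n_structures))

    green_clean = np.zeros(dims)
    red_clean = np.zeros(dims)
    coloc_clean = np.zeros(dims)
    margin = 5
    for i in range(truth.n_structures):
        center = [rng.uniform(margin, d - margin) for d in dims]
        radius = rng.uniform(3.0, 4.5)
        shell = _shell_mask(dims, center, radius)
        green_clean[shell] += truth.photon_scale
        if i < n_coloc:
            red_clean[shell] += truth.photon_scale
            coloc_clean[shell] += truth.photon_scale

    sig = truth.psf_sigma
    green_blur = ndimage.gaussian_filter(green_clean, sig)
    red_blur = ndimage.gaussian_filter(red_clean, sig)
    coloc_blur = ndimage.gaussian_filter(coloc_clean, sig)

    if truth.background > 0:
        support_cut = truth.background + 4.0 * np.sqrt(truth.background)
    else:
        peak = green_blur.max()
        support_cut = 0.05 * peak if peak > 0 else np.inf
    green_support = green_blur >= support_cut
    coloc_support = coloc_blur >= support_cut
    labels = np.zeros(dims, dtype=np.uint8)
    labels[green_support] = LABEL_GREEN_ONLY
    labels[coloc_support] = LABEL_COLOC

    green = rng.poisson(green_blur + truth.background).astype(float)
    red = rng.poisson(red_blur + truth.background).astype(float)
    return green, red, labels
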