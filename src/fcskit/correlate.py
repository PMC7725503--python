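"""Auto- and cross-correlation of binned fluorescence intensity traces.

The correlation estimator is the symmetric-normalized raw correlation

    G(tau) = <F(t) F(t+tau)> / (<F(t)> <F(t+tau)>)

so an uncorrelated signal converges to 1 and fitted offsets sit near 1.
Lag grids follow a multi-tau scheme: a block of linearly spaced lags at the
native bin width, then cascades in which the trace is rebinned by pairwise
summation (bin width doubles) and half as many lags are appended per cascade.
This covers microseconds-to-seconds lags at near-logarithmic cost, which is
what diffusion-driven fluctuation decays require.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "IntensityTrace",
    "CorrelationCurve",
    "IncompatibleTraceError",
    "UndefinedNormalizationError",
    "multi_tau_correlate",
    "brute_force_correlate",
    "per_lag_spread",
]


class IncompatibleTraceError(ValueError):
    """Two traces cannot be correlated (unequal length or bin time)."""


class UndefinedNormalizationError(ValueError):
    """Correlation normalization undefined (zero-mean trace)."""


@dataclass(frozen=True)
class IntensityTrace:
    """Uniformly binned photon-count time series for one detection channel.

    Parameters
    ----------
    bin_time : float
        Bin width in seconds, > 0.
    counts : ndarray
        Non-negative counts per bin, length >= 2.
    channel : str
        Channel label, e.g. ``"G"`` or ``"R"``.
    """

    bin_time: float
    counts: np.ndarray
    channel: str = "G"

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if self.bin_time <= 0:
            raise ValueError(f"bin_time must be > 0, got {self.bin_time}")
        if counts.ndim != 1 or counts.size < 2:
            raise ValueError("counts must be a 1-D array of length >= 2")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def duration(self) -> float:
        return self.bin_time * self.counts.size

    @property
    def mean_rate(self) -> float:
        """Mean count rate in Hz."""
        return float(np.mean(self.counts)) / self.bin_time


@dataclass
class CorrelationCurve:
    """Correlation curve: lag times, G values and optional per-lag spread.

    ``channel_pair`` tags the origin: ``"GG"``/``"RR"`` for autocorrelations,
    ``"GR"`` for the cross-correlation.
    """

    lags: np.ndarray
    G: np.ndarray
    sd: Optional[np.ndarray] = None
    channel_pair: str = "GG"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.shape != self.G.shape:
            raise ValueError("lags and G must have the same shape")
        if np.any(self.lags <= 0):
            raise ValueError("lags must be strictly positive")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.G.shape:
                raise ValueError("sd must match G in length")
            if np.any(self.sd < 0):
                raise ValueError("sd must be non-negative")

    def with_sd(self, sd: np.ndarray) -> "CorrelationCurve":
        return replace(self, sd=np.asarray(sd, dtype=float))


def _check_pair(a: IntensityTrace, b: IntensityTrace) -> None:
    if a.counts.size != b.counts.size or not np.isclose(a.bin_time, b.bin_time):
        raise IncompatibleTraceError(
            "traces must share length and bin_time: "
            f"({a.counts.size}, {a.bin_time}) vs ({b.counts.size}, {b.bin_time})"
        )
    if np.all(a.counts == 0) or np.all(b.counts == 0):
        raise UndefinedNormalizationError("all-zero trace has no defined normalization")


def _g_at_lag(a: np.ndarray, b: np.ndarray, k: int) -> float:
    # Symmetric normalization over the overlapping window: means of the
    # leading segment of a and the trailing segment of b.
    x = a[: a.size - k]
    y = b[k:]
    mx = x.mean()
    my = y.mean()
    if mx == 0.0 or my == 0.0:
        return np.nan
    return float(np.dot(x, y) / x.size / (mx * my))


def multi_tau_correlate(
    trace_a: IntensityTrace,
    trace_b: IntensityTrace | None = None,
    points_per_cascade: int = 16,
) -> CorrelationCurve:
    """Correlate two traces on a multi-tau lag grid.

    With ``trace_b`` omitted (or identical to ``trace_a``) this is the
    autocorrelation; otherwise the cross-correlation.  The grid starts with
    ``points_per_cascade`` linear lags at the native bin width; each further
    cascade rebins the counts by pairwise summation (doubling the bin width)
    and contributes ``points_per_cascade // 2`` lags, up to lags of
    duration / 8.

    Returns a :class:`CorrelationCurve` normalized so that an uncorrelated
    signal converges to 1.
    """
    auto = trace_b is None or trace_b is trace_a
    if trace_b is None:
        trace_b = trace_a
    if points_per_cascade < 4:
        raise ValueError("points_per_cascade must be >= 4")
    _check_pair(trace_a, trace_b)

    a = trace_a.counts.astype(float)
    b = trace_b.counts.astype(float)
    dt = trace_a.bin_time
    max_lag = trace_a.duration / 8.0

    lags: list[float] = []
    gs: list[float] = []

    # linear cascade
    for k in range(1, points_per_cascade + 1):
        tau = k * dt
        if tau > max_lag or k >= a.size:
            break
        lags.append(tau)
        gs.append(_g_at_lag(a, b, k))

    # doubling cascades
    level_dt = dt
    start = points_per_cascade
    half = points_per_cascade // 2
    while True:
        n = (a.size // 2) * 2
        if n < 4:
            break
        a = a[:n:2] + a[1:n:2]
        b = b[:n:2] + b[1:n:2]
        level_dt *= 2
        start //= 2
        added = False
        for k in range(start + 1, start + half + 1):
            tau = k * level_dt
            if tau > max_lag or k >= a.size:
                break
            lags.append(tau)
            gs.append(_g_at_lag(a, b, k))
            added = True
        start += half
        if not added:
            break

    pair = f"{trace_a.channel}{trace_a.channel}" if auto else f"{trace_a.channel}{trace_b.channel}"
    return CorrelationCurve(
        lags=np.array(lags),
        G=np.array(gs),
        channel_pair=pair,
        meta={
            "bin_time_s": trace_a.bin_time,
            "duration_s": trace_a.duration,
            "points_per_cascade": points_per_cascade,
        },
    )


def brute_force_correlate(
    trace_a: IntensityTrace,
    trace_b: IntensityTrace | None = None,
    lags_bins: np.ndarray | None = None,
) -> CorrelationCurve:
    """Direct O(N*L) correlation at integer-bin lags, no rebinning.

    Reference estimator used to validate the multi-tau scheme; identical
    normalization, evaluated on the raw bins at every requested lag.
    """
    if trace_b is None:
        trace_b = trace_a
    _check_pair(trace_a, trace_b)
    a = trace_a.counts.astype(float)
    b = trace_b.counts.astype(float)
    if lags_bins is None:
        lags_bins = np.arange(1, min(a.size // 8, 256))
    lags_bins = np.asarray(lags_bins, dtype=int)
    gs = np.array([_g_at_lag(a, b, int(k)) for k in lags_bins])
    return CorrelationCurve(
        lags=lags_bins * trace_a.bin_time,
        G=gs,
        channel_pair=f"{trace_a.channel}{trace_b.channel}",
    )


def per_lag_spread(
    trace_a: IntensityTrace,
    trace_b: IntensityTrace | None = None,
    n_segments: int = 10,
    points_per_cascade: int = 16,
) -> CorrelationCurve:
    """Estimate per-lag standard deviation of G by segment-wise correlation.

    The trace is cut into ``n_segments`` equal pieces, each correlated
    independently; the returned curve carries the mean G per lag with the
    across-segment SD divided by sqrt(n_segments) as the error of the mean,
    usable as fit weights.

    If the trace is too short to give >= 100 bins per segment, the full-trace
    curve is returned unweighted and a warning is logged.
    """
    import logging

    if trace_b is None:
        trace_b = trace_a
    _check_pair(trace_a, trace_b)
    seg_len = trace_a.counts.size // n_segments
    if seg_len < 100:
        logging.getLogger(__name__).warning(
            "trace too short for %d segments (%d bins each); "
            "returning unweighted full-trace correlation",
            n_segments,
            seg_len,
        )
        return multi_tau_correlate(trace_a, trace_b, points_per_cascade)

    curves = []
    for i in range(n_segments):
        sl = slice(i * seg_len, (i + 1) * seg_len)
        sa = IntensityTrace(trace_a.bin_time, trace_a.counts[sl], trace_a.channel)
        sb = IntensityTrace(trace_b.bin_time, trace_b.counts[sl], trace_b.channel)
        curves.append(multi_tau_correlate(sa, sb, points_per_cascade))

    # identical segment lengths -> identical lag grids
    lags = curves[0].lags
    G = np.vstack([c.G for c in curves])
    mean = G.mean(axis=0)
    sd = G.std(axis=0, ddof=0) / np.sqrt(n_segments)
    pair = curves[0].channel_pair
    return CorrelationCurve(lags=lags, G=mean, sd=sd, channel_pair=pair,
                            meta={"n_segments": n_segments})
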