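"""Dual-channel 3D colocalization: auto-threshold, ICA scores, masks.

The pipeline segments two registered z-stacks with a joint automatic
threshold (a Costes-style descending search, using the intensity correlation
quotient of the below-threshold voxels as the stopping statistic), scores
each foreground voxel by intensity correlation analysis (the sign of the
product of the two channels' deviations from their foreground means)
modulated by a distance weight (proximity to the nearest second-channel
foreground voxel, measured in physical units against the PSF width) and an
intensity weight, and classifies foreground voxels into colocalized and
channel-exclusive masks.

In source/target mapping for a secreted ligand, voxels where the ligand
(green) colocalizes with a membrane reporter of the producing cells (red)
constitute the source regions; green-only voxels mark the distal target
regions the ligand has spread into.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageStackPair",
    "ColocParams",
    "ColocResult",
    "ThresholdError",
    "EmptyForegroundError",
    "auto_threshold",
    "icq",
    "coloc_score",
    "classify_and_mask",
    "map_source_target",
]


class ThresholdError(ValueError):
    """Channel degenerate (constant); no threshold exists."""


class EmptyForegroundError(ValueError):
    """No voxels above threshold."""


@dataclass
class ImageStackPair:
    """Two registered 3D volumes (z, y, x) with a physical voxel size in µm."""

    A: np.ndarray
    B: np.ndarray
    voxel_size: tuple = (0.5, 0.2, 0.2)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.shape != self.B.shape:
            raise ValueError("channel volumes must share dimensions")
        if self.A.ndim != 3:
            raise ValueError("volumes must be 3-D (z, y, x)")
        if np.any(self.A < 0) or np.any(self.B < 0):
            raise ValueError("intensities must be non-negative")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths")

    def swapped(self) -> "ImageStackPair":
        return ImageStackPair(self.B, self.A, self.voxel_size)


@dataclass(frozen=True)
class ColocParams:
    """Tunables of the scoring scheme.

    sigma_d: distance-weight scale in µm (the PSF sigma); threshold_step:
    the descending-search step as a fraction of the intensity range;
    min_voxels: connected components smaller than this are dropped from the
    final masks (27 = a 3x3x3 neighborhood).
    """

    sigma_d: float = 0.25
    threshold_step: float = 0.01
    score_cut: float = 0.0
    min_voxels: int = 27


@dataclass
class ColocResult:
    """Thresholds, per-voxel scores, masks and summary statistics."""

    t_A: float
    t_B: float
    score: np.ndarray
    coloc_mask: np.ndarray
    a_only_mask: np.ndarray
    b_only_mask: np.ndarray
    ICQ: float
    summary: dict = field(default_factory=dict)


def icq(a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Intensity correlation quotient over ``mask`` (default: all voxels).

    Fraction of voxels whose deviations from the channel means share a sign,
    minus 0.5; ranges over [-0.5, 0.5], 0 for independent channels.
    """
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    av = a[mask]
    bv = b[mask]
    if av.size == 0:
        raise ValueError("empty mask")
    pdm = (av - av.mean()) * (bv - bv.mean())
    return float(np.mean(pdm > 0) - 0.5)


def auto_threshold(pair: ImageStackPair, step: float = 0.01) -> tuple[float, float]:
    """Joint automatic threshold for the two channels.

    Candidate threshold pairs run along the orthogonal trend of B against A
    (so the pair descends both channels proportionally); starting from the
    top, the search selects the lowest thresholds at which the voxels below
    both thresholds are uncorrelated or anti-correlated (ICQ <= 0).
    Deterministic given the input volumes.
    """
    a = pair.A.ravel()
    b = pair.B.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ThresholdError("constant channel; cannot threshold")
    # regression line of B on A over all voxels
    slope, intercept = np.polyfit(a, b, 1)
    if slope <= 0:
        # no positive covariation: fall back to matching quantile descent
        slope, intercept = np.std(b) / max(np.std(a), 1e-12), b.mean() - a.mean()

    lo, hi = a.min(), a.max()
    n_steps = int(round(1.0 / step))
    # start one step below the maximum so the selected foreground is never
    # empty; stop at the first (highest) threshold pair whose below-set is
    # uncorrelated or anti-correlated
    t_a, t_b = hi, slope * hi + intercept
    for i in range(n_steps - 1, 0, -1):
        t_a = lo + (hi - lo) * i / n_steps
        t_b = slope * t_a + intercept
        below = (pair.A < t_a) & (pair.B < t_b)
        if below.sum() < 100:
            continue
        av = pair.A[below]
        bv = pair.B[below]
        pdm = (av - av.mean()) * (bv - bv.mean())
        below_icq = np.mean(pdm > 0) - 0.5
        if below_icq <= 0:
            break
    t_b = float(np.clip(t_b, pair.B.min(), pair.B.max()))
    return float(t_a), t_b


def coloc_score(
    pair: ImageStackPair,
    thresholds: tuple[float, float],
    params: ColocParams = ColocParams(),
) -> np.ndarray:
    """Per-voxel colocalization score in [-1, 1] for the A-orientation.

    For A-foreground voxels: the ICA indicator sign((A - mean_A)(B - mean_B))
    with channel means over the joint foreground, multiplied by a Gaussian
    distance weight exp(-d^2 / 2 sigma_d^2) where d is the physical distance
    to the nearest B-foreground voxel, and by an intensity weight
    min(A/mean_A, B/mean_B, 1) with below-threshold intensities set to zero.
    Background voxels score 0.
    """
    t_a, t_b = thresholds
    fg_a = pair.A > t_a
    fg_b = pair.B > t_b
    if not fg_a.any() or not fg_b.any():
        raise EmptyForegroundError("no foreground voxels above threshold")

    mean_a = pair.A[fg_a].mean()
    mean_b = pair.B[fg_b].mean()
    pdm = (pair.A - mean_a) * (pair.B - mean_b)
    indicator = np.sign(pdm)

    # physical distance to the nearest B-foreground voxel
    dist = ndimage.distance_transform_edt(~fg_b, sampling=pair.voxel_size)
    w_d = np.exp(-(dist ** 2) / (2.0 * params.sigma_d ** 2))

    a_eff = np.where(fg_a, pair.A, 0.0)
    b_eff = np.where(fg_b, pair.B, 0.0)
    w_i = np.minimum(np.minimum(a_eff / mean_a, b_eff / mean_b), 1.0)

    score = np.clip(indicator * w_d * w_i, -1.0, 1.0)
    score[~fg_a] = 0.0
    return score


def classify_and_mask(
    pair: ImageStackPair,
    params: ColocParams = ColocParams(),
    thresholds: Optional[tuple[float, float]] = None,
) -> ColocResult:
    """Threshold, score and classify a stack pair into disjoint masks.

    Colocalized voxels are A-foreground voxels whose score exceeds
    ``params.score_cut``; the remaining A-foreground is A-only and the
    B-foreground outside the colocalized set is B-only.  Connected
    components smaller than ``params.min_voxels`` are removed from each
    mask.  The ICQ over the joint foreground summarizes the overall
    correlation.
    """
    if thresholds is None:
        thresholds = auto_threshold(pair, step=params.threshold_step)
    t_a, t_b = thresholds
    score = coloc_score(pair, thresholds, params)
    fg_a = pair.A > t_a
    fg_b = pair.B > t_b

    coloc = fg_a & (score > params.score_cut)
    # PDM sign flips punch single-voxel holes at structure edges; a closing
    # confined to the A-foreground repairs them; union keeps the closing
    # strictly additive (scipy erodes at array borders otherwise)
    closed = ndimage.binary_closing(coloc, structure=np.ones((3, 3, 3)))
    coloc = (coloc | closed) & fg_a
    # channel-exclusive = foreground in that channel only; joint-foreground
    # voxels that did not colocalize belong to neither exclusive mask
    a_only = fg_a & ~fg_b & ~coloc
    b_only = fg_b & ~fg_a & ~coloc

    if params.min_voxels > 1:
        coloc = _drop_small(coloc, params.min_voxels)
        a_only = _drop_small(a_only, params.min_voxels)
        b_only = _drop_small(b_only, params.min_voxels)

    fg_any = fg_a | fg_b
    quotient = icq(pair.A, pair.B, fg_any)
    n_fg = int(fg_a.sum())
    result = ColocResult(
        t_A=t_a,
        t_B=t_b,
        score=score,
        coloc_mask=coloc,
        a_only_mask=a_only,
        b_only_mask=b_only,
        ICQ=quotient,
        summary={
            "threshold_A": t_a,
            "threshold_B": t_b,
            "ICQ": quotient,
            "n_foreground_A": n_fg,
            "n_foreground_B": int(fg_b.sum()),
            "n_colocalized": int(coloc.sum()),
            "n_A_only": int(a_only.sum()),
            "n_B_only": int(b_only.sum()),
            "colocalized_fraction_of_A": float(coloc.sum() / n_fg) if n_fg else 0.0,
        },
    )
    return result


def _drop_small(mask: np.ndarray, min_voxels: int) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_voxels) + 1
    return np.isin(lab, keep)


def map_source_target(
    green: np.ndarray,
    red: np.ndarray,
    voxel_size: tuple = (0.5, 0.2, 0.2),
    params: ColocParams = ColocParams(),
) -> tuple[np.ndarray, np.ndarray, ColocResult]:
    """Map ligand source and target regions from a green/red stack pair.

    The green channel carries the secreted ligand, the red channel the
    membrane reporter confined to producing cells.  Source regions are
    voxels where the two colocalize; target regions are green-only voxels.
    Returns ``(source_mask, target_mask, result)``.
    """
    pair = ImageStackPair(green, red, voxel_size)
    result = classify_and_mask(pair, params)
    return result.coloc_mask, result.a_only_mask, result
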