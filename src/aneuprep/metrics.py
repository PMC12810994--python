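"""Segmentation evaluation metrics and cross-validation statistics.

Voxel-overlap metrics (Dice similarity coefficient, sensitivity/recall,
precision), the 95th-percentile Hausdorff surface distance in mm, and
the five-fold summary statistics with normal-approximation 95%
confidence intervals mean ± 1.96·sd/√k used to compare hybrid losses.

Empty-mask conventions (common challenge practice): the DSC of two
empty masks is 1; sensitivity or precision with a zero denominator is
reported as NaN and excluded from fold means with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import BinaryMask3D, GridMismatchError, ParameterError, logger

__all__ = [
    "OverlapCounts",
    "FoldSummary",
    "overlap_counts",
    "dice_coefficient",
    "sensitivity",
    "precision",
    "hd95",
    "ci95",
    "summarize_folds",
]


@dataclass(frozen=True)
class OverlapCounts:
    """Voxelwise contingency counts between prediction and ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def overlap_counts(pred: BinaryMask3D, gt: BinaryMask3D) -> OverlapCounts:
    if pred.shape != gt.shape:
        raise GridMismatchError(f"prediction grid {pred.shape} != truth grid {gt.shape}")
    p, g = pred.data, gt.data
    return OverlapCounts(
        tp=int(np.sum(p & g)),
        fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)),
        tn=int(np.sum(~p & ~g)),
    )


def dice_coefficient(counts: OverlapCounts) -> float:
    """DSC = 2TP / (2TP + FP + FN); two empty masks score 1."""
    den = 2 * counts.tp + counts.fp + counts.fn
    if den == 0:
        return 1.0
    return 2.0 * counts.tp / den


def sensitivity(counts: OverlapCounts) -> float:
    """Recall TP / (TP + FN); NaN when the ground truth is empty."""
    den = counts.tp + counts.fn
    if den == 0:
        warnings.warn("sensitivity undefined: empty ground truth", stacklevel=2)
        return float("nan")
    return counts.tp / den


def precision(counts: OverlapCounts) -> float:
    """TP / (TP + FP); NaN when the prediction is empty."""
    den = counts.tp + counts.fp
    if den == 0:
        warnings.warn("precision undefined: empty prediction", stacklevel=2)
        return float("nan")
    return counts.tp / den


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def _surface_points_mm(mask: BinaryMask3D) -> np.ndarray:
    """Centres (mm) of boundary voxels: true voxels with a false 6-neighbour.

    The volume border counts as false, so surface voxels at the edge of
    the grid are included.
    """
    interior = ndimage.binary_erosion(mask.data, structure=_FACE_STRUCT, border_value=0)
    boundary = mask.data & ~interior
    idx = np.argwhere(boundary)
    return idx * np.asarray(mask.spacing)


def hd95(pred: BinaryMask3D, gt: BinaryMask3D, spacing=None) -> float:
    """95th-percentile symmetric Hausdorff surface distance in mm.

    For each direction, nearest-surface distances are collected from
    every boundary voxel of one mask to the other's boundary
    (voxel-centre to voxel-centre, anisotropic spacing respected) and
    their 95th percentile taken; the result is the larger of the two
    directed values.  Lower is better; identical masks give 0.
    """
    if pred.shape != gt.shape:
        raise GridMismatchError(f"prediction grid {pred.shape} != truth grid {gt.shape}")
    if spacing is not None:
        pred = BinaryMask3D(data=pred.data, spacing=spacing)
        gt = BinaryMask3D(data=gt.data, spacing=spacing)
    if pred.n_true == 0 or gt.n_true == 0:
        raise ParameterError("hd95 undefined for an empty mask")
    a = _surface_points_mm(pred)
    b = _surface_points_mm(gt)
    d_ab = cKDTree(b).query(a, k=1)[0]
    d_ba = cKDTree(a).query(b, k=1)[0]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def ci95(mean: float, sd: float, k: int):
    """Normal-approximation 95% CI over k folds: mean ∓ 1.96·sd/√k.

    The 1.96 multiplier is fixed (not a t-quantile), matching how
    cross-validation intervals are conventionally reported for these
    fold counts.  Returns the unrounded (lo, hi).
    """
    if k < 2:
        raise ParameterError(f"need k >= 2 folds, got {k}")
    if sd < 0:
        raise ParameterError(f"sd must be >= 0, got {sd}")
    half = 1.96 * sd / math.sqrt(k)
    return (mean - half, mean + half)


@dataclass
class FoldSummary:
    """Per-fold values with mean, sample SD and 95% CI."""

    values: tuple
    mean: float
    sd: float
    ci_lo: float
    ci_hi: float

    @property
    def ci_rounded(self):
        return (round(self.ci_lo, 3), round(self.ci_hi, 3))


def summarize_folds(values) -> FoldSummary:
    """Mean, sample SD (k−1 denominator) and 95% CI of fold values.

    NaN fold values (undefined metrics on empty masks) are excluded
    with a warning; at least two finite values must remain.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    finite = arr[np.isfinite(arr)]
    if finite.size < arr.size:
        logger.warning("excluding %d undefined fold value(s)", arr.size - finite.size)
    if finite.size < 2:
        raise ParameterError(f"need >= 2 finite fold values, got {finite.size}")
    mean = float(finite.mean())
    sd = float(finite.std(ddof=1))
    lo, hi = ci95(mean, sd, finite.size)
    return FoldSummary(values=tuple(arr.tolist()), mean=mean, sd=sd, ci_lo=lo, ci_hi=hi)
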