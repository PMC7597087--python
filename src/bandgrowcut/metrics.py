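"""Segmentation quality measures.

Supervised overlap measures (Dice, precision, recall, Jaccard) compare a
binary segmentation with a binary ground truth.  Information-theoretic
measures operate on the joint label distribution P(T, S) of ground-truth
segment T and predicted segment S:

* over-segmentation entropy   OSE = H(S | T) = -sum P(T,S) log P(S|T)
* under-segmentation entropy  USE = H(T | S) = -sum P(T,S) log P(T|S)
* mutual information          MI  = H(S) + H(T) - H(S,T)
* variation of information    VoI = OSE + USE

Natural logarithms are used throughout; only ratios of OSE/USE are
typically compared, where the base cancels.

Unsupervised region-homogeneity measures (foreground/background error,
uniformity, discrepancy) score a segmentation against the image itself via
squared deviation from per-region mean intensity.  Boundary agreement is
measured by the (maximum or average) Hausdorff distance between foreground
boundary pixel sets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree
from scipy.spatial.distance import directed_hausdorff

__all__ = [
    "ConfusionCounts",
    "SupervisedMetrics",
    "RegionErrors",
    "MetricReport",
    "EmptyForegroundError",
    "confusion_counts",
    "supervised_metrics",
    "joint_distribution",
    "ose",
    "use",
    "mutual_information",
    "variation_of_information",
    "region_errors",
    "discrepancy",
    "hausdorff",
    "average_hausdorff",
    "metric_report",
    "aggregate_reports",
]


class EmptyForegroundError(ValueError):
    """Raised when a boundary-distance metric meets an empty foreground."""


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SupervisedMetrics:
    counts: ConfusionCounts
    dice: float
    precision: float
    recall: float
    jaccard: float


def confusion_counts(seg: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts, foreground (truthy) as the positive class."""
    seg = np.asarray(seg).astype(bool)
    gt = np.asarray(gt).astype(bool)
    _check_shapes(seg, gt)
    tp = int((seg & gt).sum())
    fp = int((seg & ~gt).sum())
    fn = int((~seg & gt).sum())
    tn = int((~seg & ~gt).sum())
    return ConfusionCounts(tp, fp, fn, tn)


def supervised_metrics(seg: np.ndarray, gt: np.ndarray) -> SupervisedMetrics:
    """Dice, precision, recall and Jaccard for binary masks.

    Degenerate conventions (documented for reproducibility): with both
    foregrounds empty all four scores are 1; with exactly one side empty
    they are 0 (except the trivially-empty precision/recall denominator,
    which also scores 0).
    """
    c = confusion_counts(seg, gt)
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return SupervisedMetrics(c, 1.0, 1.0, 1.0, 1.0)
    dice = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    jaccard = c.tp / (c.tp + c.fp + c.fn)
    return SupervisedMetrics(c, dice, precision, recall, jaccard)


def joint_distribution(
    seg: np.ndarray, gt: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint relative frequencies P(T, S) over (gt segment, predicted segment).

    Returns (P, t_labels, s_labels) where P[i, j] is the fraction of pixels
    with gt label t_labels[i] and predicted label s_labels[j].
    """
    seg = np.asarray(seg)
    gt = np.asarray(gt)
    _check_shapes(seg, gt)
    t_vals, t_idx = np.unique(gt, return_inverse=True)
    s_vals, s_idx = np.unique(seg, return_inverse=True)
    counts = np.zeros((t_vals.size, s_vals.size), dtype=np.int64)
    np.add.at(counts, (t_idx.ravel(), s_idx.ravel()), 1)
    return counts / counts.sum(), t_vals, s_vals


def _conditional_entropy(joint: np.ndarray, axis: int) -> float:
    """H(axis-variable | other variable) from a joint table, natural log."""
    marg = joint.sum(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(marg > 0, joint / marg, 0.0)
        terms = np.where(joint > 0, joint * np.log(cond), 0.0)
    return float(-terms.sum()) + 0.0  # avoid negative zero


def ose(seg: np.ndarray, gt: np.ndarray) -> float:
    """Over-segmentation entropy H(S | T): how ground-truth segments shatter."""
    joint, _, _ = joint_distribution(seg, gt)
    return _conditional_entropy(joint, axis=1)


def use(seg: np.ndarray, gt: np.ndarray) -> float:
    """Under-segmentation entropy H(T | S): how predicted segments merge truth."""
    joint, _, _ = joint_distribution(seg, gt)
    return _conditional_entropy(joint, axis=0)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information(seg: np.ndarray, gt: np.ndarray) -> float:
    """MI between predicted and ground-truth labelling, H(S)+H(T)-H(S,T)."""
    joint, _, _ = joint_distribution(seg, gt)
    h_t = _entropy(joint.sum(axis=1))
    h_s = _entropy(joint.sum(axis=0))
    h_ts = _entropy(joint.ravel())
    return max(0.0, h_s + h_t - h_ts)


def variation_of_information(seg: np.ndarray, gt: np.ndarray) -> float:
    return ose(seg, gt) + use(seg, gt)


@dataclass(frozen=True)
class RegionErrors:
    fg_error: float
    bg_error: float
    uniformity: float


def region_errors(image: np.ndarray, seg: np.ndarray) -> RegionErrors:
    """Region homogeneity: sums of squared deviation from region means.

    ``uniformity`` is the convex combination of the two errors weighted by
    the region pixel proportions.  Empty regions contribute 0.
    """
    image = np.asarray(image, dtype=np.float64)
    seg = np.asarray(seg).astype(bool)
    _check_shapes(image, seg)
    n = image.size
    errs = {}
    weights = {}
    for name, mask in (("fg", seg), ("bg", ~seg)):
        px = image[mask]
        errs[name] = float(((px - px.mean()) ** 2).sum()) if px.size else 0.0
        weights[name] = px.size / n
    uniformity = weights["fg"] * errs["fg"] + weights["bg"] * errs["bg"]
    return RegionErrors(errs["fg"], errs["bg"], uniformity)


def discrepancy(image: np.ndarray, seg: np.ndarray) -> float:
    """Squared error between the image and its per-region-mean reconstruction.

    Equals ``fg_error + bg_error`` for a binary segmentation.
    """
    image = np.asarray(image, dtype=np.float64)
    seg = np.asarray(seg)
    _check_shapes(image, seg)
    total = 0.0
    for value in np.unique(seg):
        px = image[seg == value]
        total += float(((px - px.mean()) ** 2).sum())
    return total


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with a 4-neighbour (or image border) background."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyForegroundError("foreground is empty")
    structure = np.zeros((3,) * mask.ndim, dtype=bool)
    for ax in range(mask.ndim):
        idx = [1] * mask.ndim
        for v in (0, 2):
            idx[ax] = v
            structure[tuple(idx)] = True
        idx[ax] = 1
    structure[(1,) * mask.ndim] = True
    interior = binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~interior).astype(float)


def hausdorff(seg_a: np.ndarray, seg_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between foreground boundaries (Euclidean)."""
    pa = _boundary_points(seg_a)
    pb = _boundary_points(seg_b)
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def average_hausdorff(seg_a: np.ndarray, seg_b: np.ndarray) -> float:
    """Average of the mean directed boundary distances in both directions."""
    pa = _boundary_points(seg_a)
    pb = _boundary_points(seg_b)
    d_ab = cKDTree(pb).query(pa)[0].mean()
    d_ba = cKDTree(pa).query(pb)[0].mean()
    return float((d_ab + d_ba) / 2.0)


@dataclass
class MetricReport:
    """Named scalar metrics for one segmentation; NaN where not computable."""

    dice: float = np.nan
    precision: float = np.nan
    recall: float = np.nan
    jaccard: float = np.nan
    mutual_information: float = np.nan
    ose: float = np.nan
    use: float = np.nan
    voi: float = np.nan
    uniformity: float = np.nan
    discrepancy: float = np.nan
    fg_error: float = np.nan
    bg_error: float = np.nan
    hausdorff: float = np.nan

    def as_dict(self) -> Dict[str, float]:
        return asdict(self)


def metric_report(
    seg: np.ndarray,
    gt: Optional[np.ndarray] = None,
    image: Optional[np.ndarray] = None,
) -> MetricReport:
    """Compute every metric the available inputs permit.

    Supervised metrics need ``gt``; unsupervised ones need ``image``;
    Hausdorff needs ``gt`` and non-empty foregrounds on both sides.
    """
    report = MetricReport()
    seg = np.asarray(seg)
    if gt is not None:
        sup = supervised_metrics(seg, gt)
        report.dice = sup.dice
        report.precision = sup.precision
        report.recall = sup.recall
        report.jaccard = sup.jaccard
        report.mutual_information = mutual_information(seg, gt)
        report.ose = ose(seg, gt)
        report.use = use(seg, gt)
        report.voi = report.ose + report.use
        try:
            report.hausdorff = hausdorff(seg, gt)
        except EmptyForegroundError:
            pass
    if image is not None:
        reg = region_errors(image, np.asarray(seg).astype(bool))
        report.fg_error = reg.fg_error
        report.bg_error = reg.bg_error
        report.uniformity = reg.uniformity
        report.discrepancy = discrepancy(image, np.asarray(seg).astype(bool))
    return report


def aggregate_reports(
    reports: Dict[str, Iterable[MetricReport]]
) -> pd.DataFrame:
    """Median / quartile table over per-image reports, one row per algorithm."""
    rows = []
    for name, items in reports.items():
        frame = pd.DataFrame([r.as_dict() for r in items])
        for metric in frame.columns:
            col = frame[metric].dropna()
            if col.empty:
                continue
            rows.append(
                {
                    "algorithm": name,
                    "metric": metric,
                    "median": col.median(),
                    "q1": col.quantile(0.25),
                    "q3": col.quantile(0.75),
                }
            )
    return pd.DataFrame(rows)
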