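"""Segmentation evaluation: overlap metrics, surface distances, paired test.

Per-class evaluation binarizes one-vs-rest and reports

* DSC        = 2|A∩B| / (|A| + |B|)
* Jaccard    = |A∩B| / |A∪B|            (algebraically DSC / (2 − DSC))
* sensitivity = TP / (TP + FN),  specificity = TN / (TN + FP)
* HD95       = 95th percentile of the pooled directed surface distances
               between the boundary voxels of ground truth and prediction,
               Euclidean in millimetres (voxel offsets scaled by spacing).

Degenerate inputs follow fixed conventions: with both masks empty DSC and
Jaccard are 1 and HD95 is undefined (NaN); with exactly one mask empty DSC
and Jaccard are 0 and HD95 is undefined. Undefined HD95 values are excluded
from summary means; sensitivity/specificity are NaN when their denominator
is zero. A surface voxel is a foreground voxel with at least one 6-connected
background (or out-of-volume) neighbor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .data import LabeledCase

__all__ = [
    "ConfusionCounts",
    "OverlapMetrics",
    "ClassMetrics",
    "MetricReport",
    "confusion_counts",
    "overlap_metrics",
    "hd95",
    "evaluate_case",
    "paired_t_test",
]


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int


class OverlapMetrics(NamedTuple):
    dsc: float
    jaccard: float
    sensitivity: float
    specificity: float


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def _check_extents(gt, pr):
    if gt.shape != pr.shape:
        raise ValueError(f"mask extents differ: {gt.shape} vs {pr.shape}")


def confusion_counts(gt, pr) -> ConfusionCounts:
    """Exact voxel tallies; tp+fp+tn+fn equals the total voxel count."""
    gt, pr = _as_bool(gt), _as_bool(pr)
    _check_extents(gt, pr)
    tp = int(np.count_nonzero(gt & pr))
    fp = int(np.count_nonzero(~gt & pr))
    fn = int(np.count_nonzero(gt & ~pr))
    tn = gt.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def overlap_metrics(gt, pr) -> OverlapMetrics:
    tp, fp, tn, fn = confusion_counts(gt, pr)
    a, b = tp + fn, tp + fp  # |A|, |B|
    if a == 0 and b == 0:
        dsc = jaccard = 1.0
    elif a == 0 or b == 0:
        dsc = jaccard = 0.0
    else:
        dsc = 2.0 * tp / (a + b)
        jaccard = tp / (a + b - tp)
    sensitivity = tp / (tp + fn) if tp + fn else math.nan
    specificity = tn / (tn + fp) if tn + fp else math.nan
    return OverlapMetrics(dsc=dsc, jaccard=jaccard,
                          sensitivity=sensitivity, specificity=specificity)


_SIX_CONNECTED = ndimage.generate_binary_structure(3, 1)


def surface_voxels(mask) -> np.ndarray:
    """Foreground voxels with a 6-connected background or out-of-volume neighbor."""
    mask = _as_bool(mask)
    eroded = ndimage.binary_erosion(mask, structure=_SIX_CONNECTED, border_value=0)
    return mask & ~eroded


def hd95(gt, pr, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile (linear interpolation) of pooled directed surface distances, mm.

    Returns NaN when either mask is empty (undefined; excluded from summaries).
    """
    gt, pr = _as_bool(gt), _as_bool(pr)
    _check_extents(gt, pr)
    if not gt.any() or not pr.any():
        return math.nan
    spacing = np.asarray(spacing, dtype=float)
    pts_a = np.argwhere(surface_voxels(gt)) * spacing
    pts_b = np.argwhere(surface_voxels(pr)) * spacing
    d_ab = cKDTree(pts_b).query(pts_a)[0]
    d_ba = cKDTree(pts_a).query(pts_b)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


@dataclass(frozen=True)
class ClassMetrics:
    dsc: float
    jaccard: float
    sensitivity: float
    specificity: float
    hd95_mm: float

    def as_dict(self) -> dict:
        return {
            "dsc": self.dsc,
            "jaccard": self.jaccard,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "hd95_mm": self.hd95_mm,
        }


@dataclass(frozen=True)
class MetricReport:
    per_class: dict[int, ClassMetrics]
    means: dict[str, float] = field(default_factory=dict)

    def as_rows(self) -> list[dict]:
        rows = [{"class": c, **m.as_dict()} for c, m in sorted(self.per_class.items())]
        rows.append({"class": "mean", **self.means})
        return rows


def _nan_mean(values: Sequence[float]) -> float:
    defined = [v for v in values if not math.isnan(v)]
    return float(np.mean(defined)) if defined else math.nan


def evaluate_case(case: LabeledCase, prediction, num_classes: int | None = None) -> MetricReport:
    """One-vs-rest metrics for every foreground class plus arithmetic means."""
    prediction = np.asarray(prediction)
    _check_extents(case.labels, prediction)
    if num_classes is None:
        num_classes = int(case.labels.max()) + 1
    known = set(range(num_classes))
    extra = set(np.unique(prediction)) - known
    if extra:
        raise ValueError(f"prediction contains labels {sorted(extra)} outside 0..{num_classes - 1}")

    per_class = {}
    for c in range(1, num_classes):
        gt_c = case.labels == c
        pr_c = prediction == c
        ov = overlap_metrics(gt_c, pr_c)
        per_class[c] = ClassMetrics(
            dsc=ov.dsc,
            jaccard=ov.jaccard,
            sensitivity=ov.sensitivity,
            specificity=ov.specificity,
            hd95_mm=hd95(gt_c, pr_c, case.spacing),
        )
    means = {
        name: _nan_mean([getattr(m, name) for m in per_class.values()])
        for name in ("dsc", "jaccard", "sensitivity", "specificity", "hd95_mm")
    }
    return MetricReport(per_class=per_class, means=means)


@dataclass(frozen=True)
class PairedTTest:
    t: float
    p: float
    degenerate: bool = False


def paired_t_test(scores_a: Sequence[float], scores_b: Sequence[float]) -> PairedTTest:
    """Two-sided paired t-test on fold-wise scores.

    Identical samples give (t=0, p=1); a constant nonzero offset has zero
    difference variance and is flagged degenerate instead of reporting an
    infinite statistic.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D sequences")
    if a.size < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return PairedTTest(t=0.0, p=1.0)
        return PairedTTest(t=math.copysign(math.inf, d.mean()), p=0.0, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTTest(t=float(res.statistic), p=float(res.pvalue))
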