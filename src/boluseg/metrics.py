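"""Pixel-level segmentation evaluation with bootstrap CIs and paired tests.

Predicted and ground-truth masks are compared pixel-wise inside the ROI.
Per-frame accuracy, sensitivity, specificity, IoU and Dice are aggregated by
averaging over frames (never by pooling pixels — frame-level values are what
paired significance tests and frame-set confidence intervals need).  Metrics
whose denominator is zero on a frame (e.g. IoU on a frame with empty
prediction and empty ground truth) are undefined there; they are excluded
from that metric's aggregate and counted.  95% confidence intervals use a
seeded percentile bootstrap (default 1000 resamples with replacement).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "TTestResult",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "iou",
    "dsc",
    "frame_metrics",
    "evaluate_set",
    "bootstrap_mean_ci",
    "paired_ttest",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "iou", "dsc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred_mask: np.ndarray, gt_mask: np.ndarray, roi=None) -> ConfusionCounts:
    """Pixel-wise counts; evaluation restricted to ROI pixels when given."""
    pred = np.asarray(pred_mask, dtype=bool)
    gt = np.asarray(gt_mask, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: prediction {pred.shape} vs ground truth {gt.shape}")
    if roi is not None:
        sel = roi.mask if hasattr(roi, "mask") else np.asarray(roi, dtype=bool)
        pred, gt = pred[sel], gt[sel]
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy(c: ConfusionCounts) -> float:
    d = c.total
    return (c.tp + c.tn) / d if d else nan


def sensitivity(c: ConfusionCounts) -> float:
    d = c.tp + c.fn
    return c.tp / d if d else nan


def specificity(c: ConfusionCounts) -> float:
    d = c.tn + c.fp
    return c.tn / d if d else nan


def iou(c: ConfusionCounts) -> float:
    d = c.tp + c.fp + c.fn
    return c.tp / d if d else nan


def dsc(c: ConfusionCounts) -> float:
    d = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / d if d else nan


def frame_metrics(c: ConfusionCounts) -> dict[str, float]:
    return {
        "accuracy": accuracy(c),
        "sensitivity": sensitivity(c),
        "specificity": specificity(c),
        "iou": iou(c),
        "dsc": dsc(c),
    }


def bootstrap_mean_ci(
    values, n_resamples: int = 1000, seed: int = 0, ci: float = 95.0
) -> tuple[float, float, float]:
    """Mean and seeded percentile-bootstrap CI of the mean.

    Resamples with replacement at the original sample size; returns
    (mean, lower, upper) at the 2.5/97.5 percentiles for a 95% interval.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    means = values[idx].mean(axis=1)
    half = (100.0 - ci) / 2.0
    lo, hi = np.percentile(means, [half, 100.0 - half])
    return float(values.mean()), float(lo), float(hi)


@dataclass
class MetricReport:
    """Per-frame metric table plus bootstrap-aggregated summary."""

    per_frame: pd.DataFrame  # one row per frame, columns METRIC_NAMES
    summary: pd.DataFrame  # index METRIC_NAMES, columns mean/ci_lo/ci_hi/n_defined
    n_frames: int
    ci_method: str = "percentile bootstrap, 1000 resamples"


def evaluate_set(
    pred_masks,
    gt_masks,
    roi=None,
    n_resamples: int = 1000,
    seed: int = 0,
) -> MetricReport:
    """Evaluate aligned lists of predicted and ground-truth masks."""
    if len(pred_masks) != len(gt_masks):
        raise ValueError("prediction and ground-truth lists must align")
    if len(pred_masks) == 0:
        raise ValueError("no frames to evaluate")
    rows = [frame_metrics(confusion(p, g, roi)) for p, g in zip(pred_masks, gt_masks)]
    per_frame = pd.DataFrame(rows)

    summary_rows = {}
    for name in METRIC_NAMES:
        vals = per_frame[name].dropna().to_numpy()
        if vals.size:
            mean, lo, hi = bootstrap_mean_ci(vals, n_resamples=n_resamples, seed=seed)
        else:
            mean = lo = hi = nan
        summary_rows[name] = {"mean": mean, "ci_lo": lo, "ci_hi": hi, "n_defined": int(vals.size)}
    summary = pd.DataFrame(summary_rows).T.astype({"n_defined": int})
    return MetricReport(
        per_frame=per_frame,
        summary=summary,
        n_frames=len(pred_masks),
        ci_method=f"percentile bootstrap, {n_resamples} resamples",
    )


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    n: int
    zero_variance: bool = False


def paired_ttest(values_a, values_b) -> TTestResult:
    """Two-sided paired t-test on per-frame differences.

    Zero variance of the differences (e.g. identical inputs) makes the
    statistic undefined; this is reported explicitly instead of a division
    by zero.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        return TTestResult(statistic=nan, pvalue=nan, n=a.size, zero_variance=True)
    res = stats.ttest_rel(a, b)
    return TTestResult(statistic=float(res.statistic), pvalue=float(res.pvalue), n=a.size)
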