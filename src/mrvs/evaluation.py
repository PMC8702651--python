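"""Segmentation-accuracy metrics and test-retest repeatability statistics.

Accuracy against a manually annotated ground truth is summarized by
sensitivity, specificity, accuracy, relative vessel volume difference
(VVD), Dice similarity coefficient (DSC) and Matthews correlation
coefficient (MCC).  Repeatability of a metric measured k times per subject
is summarized by the within-subject standard deviation Sw, the coefficient
of variation CoV = 100 * Sw / overall mean, and the one-way random-effects
intraclass correlation ICC(1,1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_geometry import ValidationError

__all__ = [
    "EvalReport",
    "RepeatabilityReport",
    "confusion_counts",
    "eval_metrics",
    "evaluate_masks",
    "within_subject_sd",
    "coefficient_of_variation",
    "intraclass_correlation",
    "repeatability_report",
]


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    vvd: float
    dsc: float
    mcc: float


@dataclass
class RepeatabilityReport:
    """Per-metric Sw / CoV / ICC over a balanced subjects x repeats table."""

    table: pd.DataFrame  # index = metric, columns = [sw, cov_pct, icc]
    n_subjects: int
    n_repeats: int


def confusion_counts(pred_mask: np.ndarray, gt_mask: np.ndarray):
    """Pixelwise (tp, fp, tn, fn); foreground = vessel."""
    pred = np.asarray(pred_mask, bool)
    gt = np.asarray(gt_mask, bool)
    if pred.shape != gt.shape:
        raise ValidationError("pred_mask and gt_mask shapes differ")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    tn = int((~pred & ~gt).sum())
    return tp, fp, tn, fn


def eval_metrics(tp: int, fp: int, tn: int, fn: int) -> EvalReport:
    """Summary metrics from confusion counts.

    VVD is the vessel volume (area) difference relative to the ground-truth
    volume: |(tp+fp) - (tp+fn)| / (tp+fn).  With an empty ground truth the
    foreground-referenced metrics (SE, DSC, VVD) are NaN.  MCC is 0 when any
    marginal is empty.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValidationError("confusion counts must be >= 0")
    total = tp + fp + tn + fn
    nan = float("nan")
    gt_pos = tp + fn
    se = tp / gt_pos if gt_pos else nan
    sp = tn / (tn + fp) if (tn + fp) else nan
    acc = (tp + tn) / total if total else nan
    dsc = 2 * tp / (2 * tp + fp + fn) if gt_pos or (tp + fp) else nan
    vvd = abs((tp + fp) - gt_pos) / gt_pos if gt_pos else nan
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return EvalReport(tp, fp, tn, fn, se, sp, acc, vvd, dsc, mcc)


def evaluate_masks(pred_mask: np.ndarray, gt_mask: np.ndarray) -> EvalReport:
    """Convenience wrapper: confusion counts then summary metrics."""
    return eval_metrics(*confusion_counts(pred_mask, gt_mask))


def _as_table(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("values: expected a subjects x repeats table")
    if arr.shape[1] < 2:
        raise ValidationError("values: every subject needs >= 2 repeats")
    if np.isnan(arr).any():
        raise ValidationError("values: table contains missing values")
    return arr


def within_subject_sd(values) -> float:
    """Sw: root of the mean per-subject sample variance (ddof = 1)."""
    arr = _as_table(values)
    return float(np.sqrt(arr.var(axis=1, ddof=1).mean()))


def coefficient_of_variation(sw: float, overall_mean: float) -> float:
    """CoV in percent: 100 * Sw / overall mean; NaN for a zero mean."""
    if overall_mean == 0:
        return float("nan")
    return 100.0 * sw / overall_mean


def intraclass_correlation(values) -> float:
    """One-way random-effects ICC(1,1) from one-way ANOVA mean squares.

    ICC = (MSB - MSW) / (MSB + (k-1) MSW); slightly negative estimates are
    possible when within-subject variance dominates.  A fully degenerate
    table (all values equal) has no defined ICC and returns NaN.
    """
    arr = _as_table(values)
    n, k = arr.shape
    if n < 2:
        raise ValidationError("values: ICC needs >= 2 subjects")
    subject_means = arr.mean(axis=1)
    grand = arr.mean()
    msb = k * ((subject_means - grand) ** 2).sum() / (n - 1)
    msw = ((arr - subject_means[:, None]) ** 2).sum() / (n * (k - 1))
    if msb == 0 and msw == 0:
        warnings.warn("degenerate table (all values equal): ICC undefined",
                      stacklevel=2)
        return float("nan")
    return float((msb - msw) / (msb + (k - 1) * msw))


def repeatability_report(metric_tables: dict[str, np.ndarray]) -> RepeatabilityReport:
    """Sw / CoV / ICC per metric over balanced subjects x repeats tables."""
    if not metric_tables:
        raise ValidationError("metric_tables: empty")
    rows = {}
    shapes = set()
    for name, values in metric_tables.items():
        arr = _as_table(values)
        shapes.add(arr.shape)
        sw = within_subject_sd(arr)
        rows[name] = {
            "sw": sw,
            "cov_pct": coefficient_of_variation(sw, float(arr.mean())),
            "icc": intraclass_correlation(arr),
        }
    if len(shapes) > 1:
        raise ValidationError("metric_tables: tables must share one shape")
    (n, k), = shapes
    table = pd.DataFrame.from_dict(rows, orient="index")[["sw", "cov_pct", "icc"]]
    table.index.name = "metric"
    return RepeatabilityReport(table=table, n_subjects=n, n_repeats=k)


def repeatability_from_wide_csv(path, subjects_col: str = "id") -> RepeatabilityReport:
    """Parse a wide CSV (columns ``<metric>_<repeat>``) into a report."""
    df = pd.read_csv(path)
    if subjects_col in df.columns:
        df = df.drop(columns=[subjects_col])
    groups: dict[str, dict[int, pd.Series]] = {}
    for col in df.columns:
        stem, _, rep = col.rpartition("_")
        if not stem or not rep.isdigit():
            raise ValidationError(
                f"column {col!r}: expected '<metric>_<repeat-number>'"
            )
        groups.setdefault(stem, {})[int(rep)] = df[col]
    tables = {
        name: np.column_stack([reps[j] for j in sorted(reps)])
        for name, reps in groups.items()
    }
    return repeatability_report(tables)
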