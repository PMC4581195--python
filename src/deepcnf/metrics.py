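"""Evaluation metrics for imbalanced per-residue binary classification.

The positive class is disorder. Threshold-based metrics (precision, balanced
accuracy, MCC) use the convention that a residue is called disordered when its
predicted probability is greater than or equal to the threshold. Metrics whose
defining ratio is 0/0 are reported as NaN (an undefined-metric signal), never
silently as 0.

By default residues are pooled across all sequences before computing a
metric; a per-sequence mode is available for per-target reporting.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import LabelSequence


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with disorder as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _pool(values) -> np.ndarray:
    if isinstance(values, LabelSequence):
        values = [values]
    arrays = []
    for v in values if isinstance(values, (list, tuple)) else [values]:
        if isinstance(v, LabelSequence):
            dense, _ = v.compressed()
            arrays.append(dense.states)
        else:
            arrays.append(np.asarray(v).ravel())
    return np.concatenate(arrays) if len(arrays) > 1 else arrays[0]


def confusion(predicted, truth) -> ConfusionCounts:
    """Pool predictions and truth (arrays or LabelSequences) into confusion counts."""
    p = _pool(predicted).astype(int)
    t = _pool(truth).astype(int)
    if p.shape != t.shape:
        raise ValueError(f"prediction length {p.shape} != truth length {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (t == 1))),
        fp=int(np.sum((p == 1) & (t == 0))),
        tn=int(np.sum((p == 0) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
    )


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN when nothing was called positive."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else math.nan


def balanced_accuracy(c: ConfusionCounts) -> float:
    """0.5 * (sensitivity + specificity); NaN when either class is absent."""
    pos, neg = c.tp + c.fn, c.tn + c.fp
    if pos == 0 or neg == 0:
        return math.nan
    return 0.5 * (c.tp / pos + c.tn / neg)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; NaN when any marginal sum is zero."""
    denom = (
        (c.tp + c.fp) * (c.tn + c.fp) * (c.tp + c.fn) * (c.tn + c.fn)
    )
    if denom == 0:
        return math.nan
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def roc_curve(scores, truth):
    """ROC points from a threshold sweep over the distinct scores (>= convention).

    Returns (fpr, tpr, thresholds); thresholds are in decreasing order with a
    leading +inf sentinel so the curve starts at (0, 0).
    """
    s = _pool(scores).astype(float)
    t = _pool(truth).astype(int)
    if s.shape != t.shape:
        raise ValueError("scores and truth have different pooled lengths")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one residue of each class")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    tp = np.cumsum(t_sorted)
    fp = np.cumsum(1 - t_sorted)
    # keep only the last point of each tie block (all tied scores flip together)
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[last]]
    return fpr, tpr, thresholds


def roc_auc(scores, truth):
    """ROC curve and area by trapezoidal integration.

    With the >= threshold convention the area equals the tie-corrected
    Mann-Whitney statistic: ties between a positive and a negative score
    contribute 1/2.
    """
    fpr, tpr, thresholds = roc_curve(scores, truth)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr, thresholds), auc


def threshold_metrics(scores, truth, threshold: float) -> dict:
    """Precision / bacc / MCC of the >=-threshold classifier, plus the counts."""
    s = _pool(scores).astype(float)
    t = _pool(truth).astype(int)
    c = confusion((s >= threshold).astype(int), t)
    return {"threshold": threshold, "precision": precision(c),
            "bacc": balanced_accuracy(c), "mcc": mcc(c), "confusion": c}


def best_mcc_threshold(scores, truth) -> tuple:
    """Threshold (among distinct scores) maximizing MCC; ties -> lowest threshold.

    Mirrors picking the operating point by best MCC on training data.
    """
    s = _pool(scores).astype(float)
    t = _pool(truth).astype(int)
    best = (-math.inf, math.inf)
    for thr in np.unique(s):
        m = mcc(confusion((s >= thr).astype(int), t))
        if math.isnan(m):
            continue
        if m > best[0] + 1e-12 or (abs(m - best[0]) <= 1e-12 and thr < best[1]):
            best = (m, float(thr))
    if not math.isfinite(best[1]):
        raise ValueError("no threshold yields a defined MCC")
    return best[1], best[0]


def per_sequence_metrics(score_seqs, truth_seqs, threshold: float = 0.2) -> pd.DataFrame:
    """Per-target metric table (one row per sequence) plus AUC where defined."""
    rows = []
    for i, (s, t) in enumerate(zip(score_seqs, truth_seqs)):
        row = {"sequence": i}
        tm = threshold_metrics(s, t, threshold)
        row.update({k: tm[k] for k in ("precision", "bacc", "mcc")})
        t_arr = _pool(t).astype(int)
        if 0 < t_arr.sum() < t_arr.size:
            row["auc"] = roc_auc(s, t)[1]
        else:
            row["auc"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("sequence")
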