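"""Multi-label screening performance metrics.

Every disease is scored as an independent binary task: non-interpolated
average precision (AP) and ROC AUC from the ranking, sensitivity /
specificity / precision from confusion counts at an operating threshold.
Macro averages are unweighted means over the classes where the per-class
value is defined. Group-stratified AP tables feed the fairness metrics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .fairness import GroupAPTable, GroupedPredictions, UndefinedMetricError

__all__ = [
    "BinaryClassCounts",
    "ScreeningReport",
    "average_precision",
    "roc_auc",
    "confusion_metrics",
    "grouped_ap_table",
    "screening_report",
]


@dataclass
class BinaryClassCounts:
    """Confusion counts of one class at one threshold."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(cls, scores, labels, threshold: float = 0.5):
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels).astype(bool)
        hard = scores >= threshold
        return cls(
            tp=int((hard & labels).sum()),
            fp=int((hard & ~labels).sum()),
            tn=int((~hard & ~labels).sum()),
            fn=int((~hard & labels).sum()),
        )


def confusion_metrics(counts: BinaryClassCounts) -> dict[str, float | None]:
    """Sensitivity, specificity and precision from confusion counts.

    A ratio with a zero denominator is reported as None (undefined), never
    as 0.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(counts.tp, counts.tp + counts.fn),
        "specificity": ratio(counts.tn, counts.tn + counts.fp),
        "precision": ratio(counts.tp, counts.tp + counts.fp),
    }


def average_precision(scores, labels) -> float:
    """Non-interpolated AP: mean precision at the rank of each positive.

    Samples are ranked by descending score with a stable sort, so tied
    scores keep their original order (AP is tie-order dependent; this
    pins the convention). Raises :class:`UndefinedMetricError` without
    positives.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UndefinedMetricError("AP undefined without positive labels")
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    ranks = np.arange(1, len(ranked) + 1)
    cum_pos = np.cumsum(ranked)
    precision_at_pos = cum_pos[ranked] / ranks[ranked]
    return float(precision_at_pos.mean())


def roc_auc(scores, labels) -> float:
    """Trapezoidal ROC AUC; ties averaged (rank-statistic equivalent)."""
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise UndefinedMetricError("AUC undefined without both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def grouped_ap_table(preds: GroupedPredictions) -> GroupAPTable:
    """Per-(class, group) AP in percent on each group's sample subset.

    Cells where the subset has no positive samples are missing (NaN) --
    the "-" cells of a published stratified table.
    """
    groups = preds.groups
    values = np.full((len(preds.classes), len(groups)), np.nan)
    for gi, g in enumerate(groups):
        mask = preds.group_mask(g)
        for ci in range(len(preds.classes)):
            try:
                ap = average_precision(preds.scores[mask, ci], preds.labels[mask, ci])
            except UndefinedMetricError:
                continue
            values[ci, gi] = 100.0 * ap
    return GroupAPTable(classes=list(preds.classes), groups=groups, values=values)


@dataclass
class ScreeningReport:
    """Per-class and macro screening performance of one model."""

    per_class: dict[str, dict[str, float | int | None]]
    macro: dict[str, float | None]
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "macro": self.macro,
            "per_class": self.per_class,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def screening_report(scores, labels, classes=None, threshold: float = 0.5) -> ScreeningReport:
    """Score a multi-label prediction matrix class by class.

    AP and AUC are reported as percent; undefined per-class values (no
    positives, or a single label value) are None and drop out of the
    macro averages, which are unweighted means over the defined classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must share shape")
    n_classes = scores.shape[1]
    if classes is None:
        classes = [f"class_{j}" for j in range(n_classes)]
    per_class: dict[str, dict] = {}
    for j, cls_ in enumerate(classes):
        s, y = scores[:, j], labels[:, j]
        try:
            ap = 100.0 * average_precision(s, y)
        except UndefinedMetricError:
            ap = None
        try:
            auc = 100.0 * roc_auc(s, y)
        except UndefinedMetricError:
            auc = None
        cm = confusion_metrics(BinaryClassCounts.from_predictions(s, y, threshold))
        per_class[cls_] = {
            "ap": ap,
            "auc": auc,
            "sensitivity": cm["sensitivity"],
            "specificity": cm["specificity"],
            "support_pos": int(np.asarray(y).astype(bool).sum()),
            "support_neg": int((~np.asarray(y).astype(bool)).sum()),
        }

    def macro_of(key: str) -> float | None:
        vals = [v[key] for v in per_class.values() if v[key] is not None]
        return float(np.mean(vals)) if vals else None

    macro = {
        "map": macro_of("ap"),
        "auc": macro_of("auc"),
        "sensitivity": macro_of("sensitivity"),
        "specificity": macro_of("specificity"),
    }
    return ScreeningReport(per_class=per_class, macro=macro, threshold=threshold)


def roc_coordinates(scores, labels) -> np.ndarray:
    """(fpr, tpr) pairs of the empirical ROC curve, for plotting export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(np.asarray(labels).astype(int), np.asarray(scores))
    return np.column_stack([fpr, tpr])
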