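"""Group-fairness metrics for multi-label disease screening.

The central quantity is the *screening quality disparity* of a disease
class k across the groups i of a sensitive attribute (sex, age bracket):

    dD_k = 100 * (max_i AP_{k,i} - min_i AP_{k,i}) / mean_i AP_{k,i}

with AP in percent.  dM and dA summarise a whole class-by-group table as
the maximum and the unweighted mean of dD over classes.  A class whose AP
is undefined for any group (no positive samples there) is excluded from
both summaries and the mean divides by the number of *scored* classes.

Three ratio-style metrics complement the disparity family, each on a
0-100 scale where 100 is perfect parity:

* PQD -- min/max ratio of group APs for one class;
* DPM -- mean over classes of the min/max ratio of group positive-
  prediction rates (demographic parity);
* EOM -- mean over classes of the min/max ratio of group true-positive
  rates (equal opportunity).

DPM and EOM need per-sample predictions, not just an AP table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedMetricError",
    "GroupAPTable",
    "GroupedPredictions",
    "DisparityReport",
    "delta_d",
    "pqd",
    "delta_m",
    "delta_a",
    "dpm",
    "eom",
    "fairness_report",
]

MISSING_MARKERS = {"", "-", "--", "nan", "na"}


class UndefinedMetricError(ValueError):
    """A fairness metric has no defined value on the given input.

    Distinct from a metric that evaluates to zero: e.g. a disparity over a
    single present group is undefined, while equal groups give zero.
    """


# ---------------------------------------------------------------------------
# containers


@dataclass
class GroupAPTable:
    """Average precision (percent) per (class, group), NaN = missing cell."""

    classes: list[str]
    groups: list[str]
    values: np.ndarray  # (n_classes, n_groups), float, NaN for missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.classes), len(self.groups)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.classes)} classes x {len(self.groups)} groups"
            )
        if not self.groups:
            raise ValueError("group list must be non-empty")
        present = self.values[~np.isnan(self.values)]
        if present.size and (present.min() < 0 or present.max() > 100):
            raise ValueError("AP values must lie in [0, 100] percent")

    def row(self, cls: str) -> dict[str, float]:
        """Present {group: AP} mapping for one class."""
        i = self.classes.index(cls)
        return {
            g: float(v)
            for g, v in zip(self.groups, self.values[i])
            if not math.isnan(v)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.classes, columns=self.groups)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GroupAPTable":
        return cls(
            classes=[str(c) for c in frame.index],
            groups=[str(g) for g in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    @classmethod
    def read(cls, path) -> "GroupAPTable":
        """Read a delimited text table: rows = classes, columns = groups.

        Lines starting with ``#`` are comments; empty cells or ``-`` mark
        missing values. The delimiter is sniffed from the header (tab or
        comma).
        """
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if not ln.lstrip().startswith("#")]
        lines = [ln for ln in lines if ln.strip()]
        if not lines:
            raise ValueError(f"no table content in {path}")
        sep = "\t" if "\t" in lines[0] else ","
        header = lines[0].split(sep)
        groups = [h.strip() for h in header[1:]]
        classes, rows = [], []
        for ln in lines[1:]:
            cells = ln.split(sep)
            classes.append(cells[0].strip())
            row = []
            for cell in cells[1:]:
                cell = cell.strip()
                if cell.lower() in MISSING_MARKERS:
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(cell))
                    except ValueError as exc:
                        raise ValueError(
                            f"non-numeric cell {cell!r} in row {cells[0]!r}"
                        ) from exc
            while len(row) < len(groups):
                row.append(np.nan)
            rows.append(row)
        return cls(classes=classes, groups=groups, values=np.array(rows))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("class\t" + "\t".join(self.groups) + "\n")
            for cls_, row in zip(self.classes, self.values):
                cells = ["-" if math.isnan(v) else f"{v:g}" for v in row]
                fh.write(cls_ + "\t" + "\t".join(cells) + "\n")


@dataclass
class GroupedPredictions:
    """Per-sample multi-label scores/labels plus a sensitive-group id."""

    scores: np.ndarray  # (n_samples, n_classes) in [0, 1]
    labels: np.ndarray  # (n_samples, n_classes) binary
    group_of: Sequence[str]  # length n_samples
    classes: list[str] | None = None
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        self.group_of = np.asarray(self.group_of)
        if self.scores.shape != self.labels.shape:
            raise ValueError(
                f"scores shape {self.scores.shape} != labels shape {self.labels.shape}"
            )
        if len(self.group_of) != self.scores.shape[0]:
            raise ValueError("every sample needs a group identifier")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.classes is None:
            self.classes = [f"class_{j}" for j in range(self.scores.shape[1])]

    @property
    def groups(self) -> list[str]:
        return sorted(set(str(g) for g in self.group_of))

    def group_mask(self, group: str) -> np.ndarray:
        return np.asarray([str(g) == group for g in self.group_of])


@dataclass
class DisparityReport:
    """Fairness summary of one model on one sensitive attribute."""

    per_class_delta_d: dict[str, float]
    delta_m: float
    delta_a: float
    pqd: dict[str, float]
    dpm: float | None
    eom: float | None
    excluded_classes: list[str] = field(default_factory=list)
    group_counts: dict[str, int] = field(default_factory=dict)
    attribute: str | None = None

    def __post_init__(self) -> None:
        overlap = set(self.excluded_classes) & set(self.per_class_delta_d)
        if overlap:
            raise ValueError(f"classes both scored and excluded: {sorted(overlap)}")
        if self.delta_a > self.delta_m + 1e-9:
            raise ValueError("delta_a cannot exceed delta_m")

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "delta_m": self.delta_m,
            "delta_a": self.delta_a,
            "dpm": self.dpm,
            "eom": self.eom,
            "per_class_delta_d": self.per_class_delta_d,
            "pqd": self.pqd,
            "excluded_classes": self.excluded_classes,
            "group_counts": self.group_counts,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_markdown(self) -> str:
        lines = [
            f"| metric | value |",
            f"|---|---|",
            f"| dM (max screening disparity) | {self.delta_m:.1f}% |",
            f"| dA (average screening disparity) | {self.delta_a:.1f}% |",
        ]
        if self.dpm is not None:
            lines.append(f"| DPM | {self.dpm:.1f} |")
        if self.eom is not None:
            lines.append(f"| EOM | {self.eom:.1f} |")
        if self.excluded_classes:
            lines.append(f"| excluded classes | {', '.join(self.excluded_classes)} |")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# per-class metrics


def _present_values(ap_by_group: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    if isinstance(ap_by_group, Mapping):
        vals = [v for v in ap_by_group.values() if v is not None]
    else:
        vals = list(ap_by_group)
    arr = np.asarray(vals, dtype=float)
    return arr[~np.isnan(arr)]


def delta_d(ap_by_group: Mapping[str, float] | Sequence[float]) -> float:
    """Screening quality disparity of one class: 100*(max-min)/mean.

    Raises :class:`UndefinedMetricError` with fewer than two present
    groups. The all-zero vector (no disparity to measure, 0/0) returns 0.
    """
    vals = _present_values(ap_by_group)
    if vals.size < 2:
        raise UndefinedMetricError(
            f"disparity undefined with {vals.size} present group(s); need >= 2"
        )
    if (vals < 0).any():
        raise ValueError("AP values must be non-negative")
    if vals.max() == 0:
        return 0.0
    return float(100.0 * (vals.max() - vals.min()) / vals.mean())


def pqd(ap_by_group: Mapping[str, float] | Sequence[float]) -> float:
    """Predictive quality disparity ratio: 100*min/max; 100 = parity."""
    vals = _present_values(ap_by_group)
    if vals.size < 2:
        raise UndefinedMetricError(
            f"ratio undefined with {vals.size} present group(s); need >= 2"
        )
    if vals.max() == 0:
        raise UndefinedMetricError("ratio undefined on all-zero AP values")
    return float(100.0 * vals.min() / vals.max())


# ---------------------------------------------------------------------------
# table-level summaries


def _scored_rows(table: GroupAPTable) -> tuple[dict[str, float], list[str]]:
    """Per-class dD over fully-present rows, plus the excluded classes."""
    scored: dict[str, float] = {}
    excluded: list[str] = []
    for cls_, row in zip(table.classes, table.values):
        if np.isnan(row).any():
            excluded.append(cls_)
        else:
            scored[cls_] = delta_d(row)
    return scored, sorted(excluded)


def delta_m(table: GroupAPTable) -> float:
    """Max screening disparity: max of per-class dD over scored classes."""
    scored, _ = _scored_rows(table)
    if not scored:
        raise UndefinedMetricError("all classes excluded; disparity undefined")
    return max(scored.values())


def delta_a(table: GroupAPTable) -> float:
    """Average screening disparity: mean dD over *scored* classes only."""
    scored, _ = _scored_rows(table)
    if not scored:
        raise UndefinedMetricError("all classes excluded; disparity undefined")
    return float(np.mean(list(scored.values())))


# ---------------------------------------------------------------------------
# prediction-based parity metrics


def _check_groups(preds: GroupedPredictions) -> list[str]:
    groups = preds.groups
    for g in groups:
        if not preds.group_mask(g).any():
            raise UndefinedMetricError(f"group {g!r} has no samples")
    if len(groups) < 2:
        raise UndefinedMetricError("need >= 2 groups for parity metrics")
    return groups


def dpm(preds: GroupedPredictions, return_excluded: bool = False):
    """Demographic parity metric.

    Mean over classes of 100 * min_i r_{k,i} / max_i r_{k,i} where r_{k,i}
    is the positive-prediction rate of class k in group i at the given
    threshold. Classes never predicted positive in any group are excluded.
    """
    groups = _check_groups(preds)
    hard = preds.scores >= preds.threshold
    rates = np.stack(
        [hard[preds.group_mask(g)].mean(axis=0) for g in groups]
    )  # (n_groups, n_classes)
    ratios, excluded = [], []
    for j, cls_ in enumerate(preds.classes):
        col = rates[:, j]
        if col.max() == 0:
            excluded.append(cls_)
        else:
            ratios.append(100.0 * col.min() / col.max())
    if not ratios:
        raise UndefinedMetricError(
            "demographic parity undefined: no class is ever predicted positive"
        )
    value = float(np.mean(ratios))
    return (value, sorted(excluded)) if return_excluded else value


def eom(preds: GroupedPredictions, return_excluded: bool = False):
    """Equality of opportunity metric.

    Mean over classes of 100 * min_i TPR_{k,i} / max_i TPR_{k,i}, taken
    over groups with at least one positive sample of class k. Classes with
    positives in fewer than two groups, or where no group attains a
    positive TPR, are excluded.
    """
    groups = _check_groups(preds)
    hard = preds.scores >= preds.threshold
    labels = preds.labels.astype(bool)
    ratios, excluded = [], []
    for j, cls_ in enumerate(preds.classes):
        tprs = []
        for g in groups:
            m = preds.group_mask(g)
            pos = labels[m, j]
            if pos.any():
                tprs.append(hard[m, j][pos].mean())
        if len(tprs) < 2 or max(tprs) == 0:
            excluded.append(cls_)
        else:
            tprs = np.asarray(tprs)
            ratios.append(100.0 * tprs.min() / tprs.max())
    if not ratios:
        raise UndefinedMetricError("equal opportunity undefined: all classes excluded")
    value = float(np.mean(ratios))
    return (value, sorted(excluded)) if return_excluded else value


# ---------------------------------------------------------------------------
# report assembly


def fairness_report(
    source: GroupAPTable | GroupedPredictions,
    attribute: str | None = None,
) -> DisparityReport:
    """Assemble a :class:`DisparityReport` from an AP table or predictions.

    With raw :class:`GroupedPredictions`, per-group AP is computed first
    (missing cells where a group has no positives) and DPM/EOM are
    included; with a bare :class:`GroupAPTable` they are marked missing.
    """
    if isinstance(source, GroupedPredictions):
        from .screening import grouped_ap_table

        table = grouped_ap_table(source)
        dpm_val = dpm(source)
        eom_val = eom(source)
        counts = {g: int(source.group_mask(g).sum()) for g in source.groups}
    elif isinstance(source, GroupAPTable):
        table, dpm_val, eom_val, counts = source, None, None, {}
    else:
        raise TypeError(
            "fairness_report needs a GroupAPTable or GroupedPredictions, "
            f"got {type(source).__name__}"
        )

    scored, excluded = _scored_rows(table)
    if not scored:
        raise UndefinedMetricError("all classes excluded; disparity undefined")
    pqds = {}
    for cls_ in scored:
        row = table.row(cls_)
        try:
            pqds[cls_] = pqd(row)
        except UndefinedMetricError:
            pass  # all-zero row: dD scored it as 0, ratio has no value
    return DisparityReport(
        per_class_delta_d=scored,
        delta_m=max(scored.values()),
        delta_a=float(np.mean(list(scored.values()))),
        pqd=pqds,
        dpm=dpm_val,
        eom=eom_val,
        excluded_classes=excluded,
        group_counts=counts,
        attribute=attribute,
    )
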