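"""Per-residue performance measures.

Scalar metrics derive from the confusion table (sensitivity, specificity,
accuracy, balanced accuracy = (Sens+Spec)/2, MCC, F1); ranking quality
from the ROC and precision-recall curves.  Metrics whose denominator is
zero are carried as an explicit ``nan`` marker and skipped during
aggregation — never silently coerced to 0, which would distort grouped
curves such as the terminal-position profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from .score_io import Dataset

#: Explicit marker for metrics with a zero denominator.
UNDEFINED = float("nan")


def is_defined(value: float) -> bool:
    return not math.isnan(value)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """Confusion-derived scalars plus optional ROC/PR curves and AUCs."""

    counts: ConfusionCounts
    sens: float
    spec: float
    acc: float
    acc_b: float
    mcc: float
    f1: float
    auc_roc: float = UNDEFINED
    auc_pr: float = UNDEFINED
    roc_points: np.ndarray | None = None  # (fpr, tpr) rows
    pr_points: np.ndarray | None = None   # (recall, precision) rows

    def scalars(self) -> dict[str, float]:
        return {
            "sens": self.sens, "spec": self.spec, "acc": self.acc,
            "acc_b": self.acc_b, "mcc": self.mcc, "f1": self.f1,
            "auc_roc": self.auc_roc, "auc_pr": self.auc_pr,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def confusion_metrics(labels, calls) -> MetricReport:
    """Scalar metrics from binary labels and calls (1 = disordered)."""
    labels = np.asarray(labels, int)
    calls = np.asarray(calls, int)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != calls.shape:
        raise ValueError("labels and calls must have equal length")
    tp = int(((labels == 1) & (calls == 1)).sum())
    fn = int(((labels == 1) & (calls == 0)).sum())
    tn = int(((labels == 0) & (calls == 0)).sum())
    fp = int(((labels == 0) & (calls == 1)).sum())
    return metrics_from_counts(ConfusionCounts(tp, fp, tn, fn))


def metrics_from_counts(c: ConfusionCounts) -> MetricReport:
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    acc = _ratio(c.tp + c.tn, c.total)
    acc_b = (sens + spec) / 2 if is_defined(sens) and is_defined(spec) else UNDEFINED
    prec = _ratio(c.tp, c.tp + c.fp)
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / mcc_den if mcc_den > 0 else UNDEFINED
    if is_defined(prec) and is_defined(sens) and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    else:
        f1 = UNDEFINED
    return MetricReport(c, sens, spec, acc, acc_b, mcc, f1)


def roc_pr_curves(labels, probabilities) -> MetricReport:
    """ROC and precision-recall curves with trapezoidal/step-sum AUCs.

    The threshold sweep visits each distinct probability once, so tied
    probabilities move along the curve in a single step.  ROC AUC is the
    trapezoid over (FPR, TPR); PR AUC is the interpolation-free step sum
    sum_i (R_i - R_{i-1}) P_i.
    """
    labels = np.asarray(labels, int)
    probabilities = np.asarray(probabilities, float)
    if not np.all(np.isfinite(probabilities)):
        raise ValueError("probabilities must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for ROC/PR curves")

    fpr, tpr, _ = roc_curve(labels, probabilities, drop_intermediate=False)
    auc_roc = float(_trapezoid_auc(fpr, tpr))
    precision, recall, _ = precision_recall_curve(labels, probabilities)
    # sklearn returns the sweep high->low ending at recall 0; reverse to
    # ascending recall and accumulate the step sum (average precision).
    rec = recall[::-1]
    prec = precision[::-1]
    auc_pr = float(np.sum(np.diff(rec, prepend=0.0) * prec))

    report = confusion_metrics(labels, (probabilities >= 0.5).astype(int))
    report.auc_roc = auc_roc
    report.auc_pr = auc_pr
    report.roc_points = np.column_stack([fpr, tpr])
    report.pr_points = np.column_stack([rec, prec])
    return report


def evaluate(labels, probabilities, call_cutoff: float = 0.5) -> MetricReport:
    """Full report: confusion scalars at ``call_cutoff`` plus both AUCs."""
    curves = roc_pr_curves(labels, probabilities)
    report = confusion_metrics(labels, (np.asarray(probabilities) >= call_cutoff).astype(int))
    report.auc_roc = curves.auc_roc
    report.auc_pr = curves.auc_pr
    report.roc_points = curves.roc_points
    report.pr_points = curves.pr_points
    return report


def overlap_coverage(labels, calls_A, calls_B):
    """Pairwise agreement of two predictors' correct calls, per class.

    overlap_pos = |TP_A ∩ TP_B| / n_pos, coverage_pos = |TP_A ∪ TP_B| /
    n_pos, and analogously for the negatives with true-negative sets.
    Returns ``(overlap_pos, coverage_pos, overlap_neg, coverage_neg)``;
    a side with no samples reports the undefined marker.
    """
    labels = np.asarray(labels, int)
    a = np.asarray(calls_A, int)
    b = np.asarray(calls_B, int)
    pos, neg = labels == 1, labels == 0
    tpa, tpb = pos & (a == 1), pos & (b == 1)
    tna, tnb = neg & (a == 0), neg & (b == 0)
    return (
        _ratio((tpa & tpb).sum(), pos.sum()),
        _ratio((tpa | tpb).sum(), pos.sum()),
        _ratio((tna & tnb).sum(), neg.sum()),
        _ratio((tna | tnb).sum(), neg.sum()),
    )


def all_coverage(labels, calls_list):
    """Union coverage of correct calls across >= 2 predictors, per class."""
    if len(calls_list) < 2:
        raise ValueError("all_coverage needs at least two call vectors")
    labels = np.asarray(labels, int)
    pos, neg = labels == 1, labels == 0
    tp_any = np.zeros_like(pos)
    tn_any = np.zeros_like(neg)
    for calls in calls_list:
        c = np.asarray(calls, int)
        tp_any |= pos & (c == 1)
        tn_any |= neg & (c == 0)
    return _ratio(tp_any.sum(), pos.sum()), _ratio(tn_any.sum(), neg.sum())


#: Terminal distances reported by the positional groupings.
TERMINAL_RANGE = range(5, 26)


def grouped_balanced_accuracy(dataset: Dataset, calls, grouping: str) -> pd.DataFrame:
    """Per-group sensitivity/specificity/balanced accuracy table.

    ``grouping`` is one of ``amino_acid`` (twenty standard residue types;
    ``X`` excluded), ``n_terminal_distance`` / ``c_terminal_distance``
    (distances 5..25 from the respective terminus, pooled across
    sequences), or ``per_sequence`` (one row per sequence, including the
    sequence's labelled disorder fraction).  Groups containing a single
    class keep their row with undefined markers.
    """
    calls = np.asarray(calls, int)
    if not dataset.is_labelled:
        raise ValueError("grouped evaluation requires labels")
    if calls.shape != (dataset.n_residues,):
        raise ValueError("calls not aligned with dataset residues")

    rows = []

    def add_row(group, mask_labels, mask_calls, extra=None):
        rep = (confusion_metrics(mask_labels, mask_calls)
               if mask_labels.size else None)
        row = {
            "group": group,
            "n": int(mask_labels.size),
            "sens": rep.sens if rep else UNDEFINED,
            "spec": rep.spec if rep else UNDEFINED,
            "acc_b": rep.acc_b if rep else UNDEFINED,
        }
        if extra:
            row.update(extra)
        rows.append(row)

    offsets = np.cumsum([0] + [len(p) for p in dataset.profiles])
    if grouping == "per_sequence":
        for p, off in zip(dataset.profiles, offsets):
            add_row(p.seq_id, p.labels, calls[off:off + len(p)],
                    extra={"disorder_fraction": float(p.labels.mean())})
    elif grouping == "amino_acid":
        res = np.array(list("".join(p.residues for p in dataset.profiles)))
        labels = np.concatenate([p.labels for p in dataset.profiles])
        for aa in sorted(set("ACDEFGHIKLMNPQRSTVWY")):
            m = res == aa
            add_row(aa, labels[m], calls[m])
    elif grouping in ("n_terminal_distance", "c_terminal_distance"):
        attr = ("n_terminal_distance" if grouping.startswith("n") else
                "c_terminal_distance")
        dist = np.concatenate([getattr(p, attr) for p in dataset.profiles])
        labels = np.concatenate([p.labels for p in dataset.profiles])
        for d in TERMINAL_RANGE:
            m = dist == d
            add_row(d, labels[m], calls[m])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return pd.DataFrame(rows)
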