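"""Metrics, permutation testing and paired model comparisons.

Predictions are pooled across the outer folds of a repeat and scored once
(pooled-then-scored); the severe class is the positive class, so recall
equals the severe-class accuracy and balanced accuracy is the mean of the
two per-class accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import AlignmentError, ArgumentError, LesionSubtypeError


@dataclass
class PerformanceRecord:
    acc_severe: float
    acc_nonsevere: float
    balanced_accuracy: float
    precision: float
    recall: float
    f1: float
    repeat_index: int = 0
    division_by_zero: bool = False

    def as_dict(self) -> dict:
        return {
            "acc_severe": self.acc_severe, "acc_nonsevere": self.acc_nonsevere,
            "balanced_accuracy": self.balanced_accuracy,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "repeat_index": self.repeat_index,
        }


def confusion_metrics(y_true, y_pred, repeat_index: int = 0) -> PerformanceRecord:
    """Score pooled predictions; severe (label 1) is the positive class.

    Any division by zero (empty class or no positive prediction) yields 0 for
    the affected metric with ``division_by_zero`` flagged.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise AlignmentError("label vectors differ in length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))

    flag = False

    def ratio(num, den):
        nonlocal flag
        if den == 0:
            flag = True
            return 0.0
        return num / den

    acc_severe = ratio(tp, tp + fn)
    acc_nonsevere = ratio(tn, tn + fp)
    precision = ratio(tp, tp + fp)
    recall = acc_severe
    f1 = (0.0 if precision + recall == 0
          else 2.0 * precision * recall / (precision + recall))
    return PerformanceRecord(
        acc_severe=acc_severe, acc_nonsevere=acc_nonsevere,
        balanced_accuracy=0.5 * (acc_severe + acc_nonsevere),
        precision=precision, recall=recall, f1=f1,
        repeat_index=repeat_index, division_by_zero=flag,
    )


def permutation_test(
    runner, labels, n_permutations: int = 500, seed: int = 0
) -> dict:
    """Label-permutation null for a pipeline's F1 score.

    ``runner(labels, seed)`` must rebuild and test the model deterministically
    and return its F1 score.  The p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_permutations)``.
    """
    if n_permutations < 1:
        raise ArgumentError("n_permutations must be >= 1")
    labels = np.asarray(labels)
    observed = float(runner(labels, seed))
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 41])
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = runner(rng.permutation(labels), seed)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_permutations)
    return {"observed_f1": observed, "null_f1": null, "p_value": float(p)}


def paired_compare(scores_a, scores_b) -> dict:
    """Two-sided paired t-test over repeats, with Cohen's d on differences."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise AlignmentError("score vectors must be 1-D and equal length")
    if a.size < 2:
        raise ArgumentError("need at least two repeats")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise LesionSubtypeError("zero-variance differences: paired t undefined")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": int(df), "p": float(p),
            "cohens_d": float(d.mean() / sd), "mean_diff": float(d.mean())}


def records_to_long_format(records: list[PerformanceRecord], model: str):
    """Violin-plot-ready long rows (model, repeat, metric, value)."""
    rows = []
    for r in records:
        for metric, value in r.as_dict().items():
            if metric == "repeat_index":
                continue
            rows.append({"model": model, "repeat": r.repeat_index,
                         "metric": metric, "value": value})
    return rows
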