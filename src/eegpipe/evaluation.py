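"""Evaluation: confusion metrics, per-subject ApEn summaries, feature comparisons.

Patient is the positive class throughout, so sensitivity is the patient
detection rate TP/(TP+FN) and specificity the control detection rate
TN/(TN+FP).  Fold accuracies are summarised as mean ± sample SD over the
folds; feature types are compared by a variance-ratio F statistic and a
paired two-sided t test over the matched fold-accuracy vectors, with no
multiple-testing correction across the comparisons (a deliberate, reported
choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "ConfusionCounts",
    "metrics",
    "pooled_confusion",
    "fold_accuracy_summary",
    "subject_apen_table",
    "ComparisonStats",
    "compare_features",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled window-level confusion counts, patient = positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def metrics(c: ConfusionCounts) -> dict:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValidationError(
            "sensitivity/specificity undefined: one class has no scored windows"
        )
    return {
        "sensitivity": c.tp / (c.tp + c.fn),
        "specificity": c.tn / (c.tn + c.fp),
        "accuracy": (c.tp + c.tn) / c.total,
    }


def pooled_confusion(fold_results) -> ConfusionCounts:
    """Pool window-level predictions of all folds into one confusion table."""
    tp = tn = fp = fn = 0
    for fold in fold_results:
        pos = fold.true_label > 0
        correct = int((fold.predicted == fold.true_label).sum())
        wrong = len(fold.predicted) - correct
        if pos:
            tp += correct
            fn += wrong
        else:
            tn += correct
            fp += wrong
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def fold_accuracy_summary(fold_results) -> dict:
    """Mean ± sample SD of the per-fold accuracies, plus subject-level votes."""
    acc = np.array([f.fold_accuracy for f in fold_results])
    votes = np.array([f.majority_label == f.true_label for f in fold_results])
    return {
        "n_folds": len(fold_results),
        "accuracy_mean": float(acc.mean()),
        "accuracy_sd": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
        "subject_vote_accuracy": float(votes.mean()),
    }


def subject_apen_table(apen_frame: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Per-subject mean ± sample SD of windowed ApEn for one channel.

    ``apen_frame`` is the long-format feature table (columns subject_id,
    group, window_index, feature_name, value) with features named
    ``apen_<channel>``.  Returns one row per subject with columns
    subject_id, group, mean, sd — the per-channel analogue of a clinical
    summary table.
    """
    name = f"apen_{channel}"
    sub = apen_frame[apen_frame["feature_name"].str.lower() == name.lower()]
    if sub.empty:
        raise ValidationError(
            f"channel {channel!r} not present in the ApEn feature table"
        )
    counts = sub.groupby("subject_id")["value"].count()
    if (counts < 2).any():
        raise ValidationError("each subject needs >= 2 windows for a mean +- SD")
    table = (
        sub.groupby(["subject_id", "group"], sort=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    table.insert(0, "channel", channel)
    return table


@dataclass(frozen=True)
class ComparisonStats:
    """ApEn-vs-other comparison over matched fold accuracies.

    ``f_statistic`` is var(other)/var(reference); ``degenerate`` flags a
    zero-variance difference vector, for which the paired t statistic is
    unbounded and the p value is reported as 0.0.
    """

    reference: str
    other: str
    f_statistic: float
    t_statistic: float
    p_value: float
    degenerate: bool = False


def compare_features(fold_accuracies: dict, reference: str = "apen") -> list:
    """Compare the reference feature's fold accuracies with every other type.

    All vectors must come from the same folds (same length, same subject
    order).  Returns one :class:`ComparisonStats` per non-reference type.
    """
    if reference not in fold_accuracies:
        raise ValidationError(f"reference feature {reference!r} missing")
    ref = np.asarray(fold_accuracies[reference], dtype=float)
    out = []
    for name, vec in fold_accuracies.items():
        if name == reference:
            continue
        v = np.asarray(vec, dtype=float)
        if len(v) != len(ref):
            raise ValidationError(
                f"fold vectors of {reference!r} and {name!r} differ in length"
            )
        var_ref = ref.var(ddof=1)
        var_other = v.var(ddof=1)
        f_stat = float(var_other / var_ref) if var_ref > 0 else float("inf")
        diff = ref - v
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff, 0.0):
                t_stat, p_val, degenerate = 0.0, 1.0, False
            else:  # constant nonzero shift: t unbounded
                t_stat = float(np.sign(diff.mean()) * np.inf)
                p_val, degenerate = 0.0, True
        else:
            t_stat, p_val = stats.ttest_rel(ref, v)
            t_stat, p_val, degenerate = float(t_stat), float(p_val), False
        out.append(
            ComparisonStats(
                reference=reference,
                other=name,
                f_statistic=f_stat,
                t_statistic=t_stat,
                p_value=p_val,
                degenerate=degenerate,
            )
        )
    return out
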