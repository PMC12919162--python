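"""Subject-wise splitting and the classification metric suite.

All partitioning is performed on subject identifiers, never on epochs:
a single outer 80/20 group split holds out test subjects entirely, and
five repeated group-shuffle splits of the remaining subjects provide
train/validation folds for model selection and early stopping.  Metrics
are epoch-level (each 3-second segment is an independent sample):
accuracy, precision, recall, per-class and macro F1, and ROC-AUC, with
zero-denominator ratios reported as missing rather than zero.  A
subject-level majority-vote report is available as a secondary view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import GroupShuffleSplit

__all__ = [
    "SplitPlan",
    "ConfusionMatrix",
    "make_split",
    "confusion_from_predictions",
    "metrics",
    "aggregate_fold_metrics",
    "subject_majority_vote",
]

POSITIVE_CLASS = "MCI"


@dataclass
class SplitPlan:
    """Outer held-out test subjects + repeated inner train/val folds."""

    outer_test_subjects: set[str]
    inner_folds: list[tuple[set[str], set[str]]]
    seed: int

    def validate(self) -> None:
        for tr, va in self.inner_folds:
            if tr & va:
                raise ValueError("inner fold train/val subject overlap")
            if (tr | va) & self.outer_test_subjects:
                raise ValueError("test subject leaked into an inner fold")

    def epoch_indices(self, subject_ids: np.ndarray, which: set[str]) -> np.ndarray:
        return np.flatnonzero(np.isin(subject_ids, sorted(which)))


@dataclass
class ConfusionMatrix:
    """Binary confusion counts with MCI as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def make_split(
    subject_ids: np.ndarray,
    labels: np.ndarray,
    seed: int,
    n_inner: int = 5,
    test_size: float = 0.2,
    val_size: float = 0.2,
    max_retries: int = 50,
) -> SplitPlan:
    """Group-shuffle partitioning at the subject level.

    Draws are re-attempted (bounded) until every partition contains both
    classes, which is required for training and for the metric suite.
    """
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    subjects, first = np.unique(subject_ids, return_index=True)
    subj_labels = labels[first]
    if min((subj_labels == c).sum() for c in np.unique(subj_labels)) < 2:
        raise ValueError("need at least 2 subjects per class")

    def draw(ids, labs, size, rs):
        gss = GroupShuffleSplit(n_splits=1, test_size=size, random_state=rs)
        tr, te = next(gss.split(ids, labs, groups=ids))
        return set(ids[tr]), set(ids[te])

    def both_classes(ss):
        got = {subj_labels[list(subjects).index(s)] for s in ss}
        return len(got) == 2

    for attempt in range(max_retries):
        train_pool, test = draw(
            subjects, subj_labels, test_size, (seed + attempt) % 2**32
        )
        if both_classes(test) and both_classes(train_pool):
            break
    else:
        raise RuntimeError("could not draw a class-covering outer split")

    pool = np.array(sorted(train_pool))
    pool_labels = np.array(
        [subj_labels[list(subjects).index(s)] for s in pool]
    )
    inner = []
    for k in range(n_inner):
        for attempt in range(max_retries):
            rs = (seed * 1000 + k * 100 + attempt + 1) % 2**32
            tr, va = draw(pool, pool_labels, val_size, rs)
            if both_classes(tr) and both_classes(va):
                inner.append((tr, va))
                break
        else:
            raise RuntimeError("could not draw a class-covering inner split")
    plan = SplitPlan(outer_test_subjects=test, inner_folds=inner, seed=seed)
    plan.validate()
    return plan


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionMatrix:
    pos_t = np.asarray(y_true) == POSITIVE_CLASS
    pos_p = np.asarray(y_pred) == POSITIVE_CLASS
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def roc_auc(y_true_pos: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic; ties count one half."""
    y = np.asarray(y_true_pos, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s))
    sorted_s = s[order]
    # average ranks for ties
    r = np.arange(1, len(s) + 1, dtype=float)
    uniq, inv, counts = np.unique(sorted_s, return_inverse=True, return_counts=True)
    cum = np.cumsum(counts)
    avg = (cum - (counts - 1) / 2.0).astype(float)
    ranks[order] = avg[inv]
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def metrics(
    cm: ConfusionMatrix,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> dict[str, float]:
    """Accuracy, precision, recall, per-class + macro F1, and AUC.

    ``scores`` are positive-class probabilities; AUC is skipped when they
    are absent.  Undefined ratios become NaN (missing), never zero.
    """
    acc = _safe_div(cm.tp + cm.tn, cm.total)
    prec = _safe_div(cm.tp, cm.tp + cm.fp)
    rec = _safe_div(cm.tp, cm.tp + cm.fn)
    f1_pos = _safe_div(2 * prec * rec, prec + rec) if prec == prec and rec == rec else float("nan")
    prec_neg = _safe_div(cm.tn, cm.tn + cm.fn)
    rec_neg = _safe_div(cm.tn, cm.tn + cm.fp)
    f1_neg = (
        _safe_div(2 * prec_neg * rec_neg, prec_neg + rec_neg)
        if prec_neg == prec_neg and rec_neg == rec_neg
        else float("nan")
    )
    out = {
        "accuracy": acc,
        "precision": prec,
        "recall": rec,
        "f1_mci": f1_pos,
        "f1_hc": f1_neg,
        "macro_f1": float(np.mean([f1_pos, f1_neg])),
    }
    if scores is not None and y_true is not None:
        out["auc"] = roc_auc(np.asarray(y_true) == POSITIVE_CLASS, scores)
    return out


def aggregate_fold_metrics(fold_reports: list[dict[str, float]]) -> dict[str, dict[str, float]]:
    """Mean +/- SD over folds for every metric present in all folds."""
    keys = set.intersection(*(set(r) for r in fold_reports))
    return {
        k: {
            "mean": float(np.nanmean([r[k] for r in fold_reports])),
            "sd": float(np.nanstd([r[k] for r in fold_reports])),
        }
        for k in sorted(keys)
    }


def subject_majority_vote(
    subject_ids: np.ndarray, y_true: np.ndarray, y_pred: np.ndarray
) -> dict[str, float]:
    """Secondary subject-level report: majority vote over a subject's epochs."""
    subject_ids = np.asarray(subject_ids)
    correct = 0
    subjects = np.unique(subject_ids)
    for s in subjects:
        idx = subject_ids == s
        votes = (np.asarray(y_pred)[idx] == POSITIVE_CLASS).mean()
        pred = POSITIVE_CLASS if votes > 0.5 else "HC"
        if pred == np.asarray(y_true)[idx][0]:
            correct += 1
    return {"subject_accuracy": correct / len(subjects), "n_subjects": len(subjects)}
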