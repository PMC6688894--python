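"""Classification metrics, ROC/AUC, stratified cross-validation and a
variance-of-Laplacian blur baseline.

The artefact class is the positive class throughout.  Balanced accuracy
defaults to the (precision + recall)/2 convention used by the reference
protocol; the standard (sensitivity + specificity)/2 variant is available
behind a flag.  Metrics with a zero denominator are reported as ``None``
(undefined), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import laplace
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold

from .phantom import CineSequence

__all__ = [
    "ConfusionCounts", "Metrics", "RocCurve", "FoldAssignment",
    "confusion", "metrics", "roc_auc", "stratified_kfold",
    "variance_of_laplacian", "evaluate_multiclass",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class Metrics:
    """``None`` marks an undefined (zero-denominator) metric."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    balanced_accuracy: float | None


@dataclass
class RocCurve:
    thresholds: np.ndarray     # descending
    tpr: np.ndarray
    fpr: np.ndarray


@dataclass
class FoldAssignment:
    """Per-repeat test-fold index for every sample; shape (repeats, n)."""

    folds: np.ndarray
    k: int
    repeats: int


def confusion(y_true, y_pred_binary) -> ConfusionCounts:
    """Binary confusion counts with artefact (=1) as the positive class."""
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred_binary, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        tn=int(np.sum((y == 0) & (p == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts, balanced_variant: str = "precision_recall") -> Metrics:
    """Accuracy, precision, recall and balanced accuracy from counts.

    ``balanced_variant="precision_recall"`` (default) returns
    (precision + recall)/2; ``"sensitivity_specificity"`` returns the
    standard (TPR + TNR)/2.
    """
    accuracy = _ratio(c.tp + c.tn, c.total)
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if balanced_variant == "precision_recall":
        ba = None if precision is None or recall is None else (precision + recall) / 2.0
    elif balanced_variant == "sensitivity_specificity":
        specificity = _ratio(c.tn, c.tn + c.fp)
        ba = None if recall is None or specificity is None else (recall + specificity) / 2.0
    else:
        raise ValueError(f"unknown balanced_variant {balanced_variant!r}")
    return Metrics(accuracy=accuracy, precision=precision, recall=recall,
                   balanced_accuracy=ba)


def roc_auc(y_true, scores) -> tuple[RocCurve, float]:
    """ROC curve (threshold sweep over unique scores) and trapezoidal AUC.

    Equivalent to the probability that a random positive outscores a random
    negative, counting ties as 1/2.  Errors if only one class is present.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("length mismatch between labels and scores")
    if np.unique(y).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr), auc


def stratified_kfold(labels, k: int = 10, repeats: int = 1, seed: int = 0) -> FoldAssignment:
    """Repeated stratified k-fold test assignment, deterministic per seed.

    Each sample lands in exactly one test fold per repeat, with per-fold
    class counts within one sample of proportional.  Errors, naming the
    class, if any class has fewer than ``k`` members.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k:
            raise ValueError(f"class {cls!r} has only {cnt} members; needs >= k={k}")
    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    folds = np.full((repeats, len(y)), -1, dtype=int)
    for split_idx, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        rep, fold = divmod(split_idx, k)
        folds[rep, test_idx] = fold
    return FoldAssignment(folds=folds, k=k, repeats=repeats)


def variance_of_laplacian(seq: CineSequence, mode: str = "reflect") -> float:
    """Mean over frames of the variance of the discrete Laplacian response.

    A no-reference blur score: blurrier sequences give lower values.
    """
    scores = [float(np.var(laplace(seq.frames[:, :, i], mode=mode)))
              for i in range(seq.n_frames)]
    return float(np.mean(scores))


def evaluate_multiclass(y_true, y_pred,
                        classes=("good", "breathing", "mistriggering")) -> dict:
    """One-vs-rest balanced accuracy per artefact class.

    Classes absent from ``y_true`` are reported as ``None`` (undefined).
    """
    y = np.asarray(y_true)
    p = np.asarray(y_pred)
    if y.shape != p.shape:
        raise ValueError("length mismatch")
    out: dict[str, float | None] = {}
    for cls in classes:
        if cls == "good":
            continue
        if not np.any(y == cls):
            out[cls] = None
            continue
        c = confusion((y == cls).astype(int), (p == cls).astype(int))
        out[cls] = metrics(c).balanced_accuracy
    return out
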