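"""Accuracy metrics and the train/test + cross-validation protocol.

The headline metric is *balanced accuracy*: the unweighted mean of the
per-class recalls (for a binary task, the mean of the true-positive and
true-negative rates), so a constant predictor scores at chance regardless
of class imbalance. Binary F1 treats the Rib / Whole Rib class as the
positive category; the ternary score is the macro-averaged F1. Model
selection stability is probed with stratified k-fold cross-validation
(k = 10 in the study protocol) reporting the mean held-out
misclassification fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError


@dataclass
class ConfusionMatrix:
    """Square count grid; rows are true classes, columns predictions."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise DataError("counts must be a nonnegative square grid")

    @classmethod
    def from_labels(cls, true, predicted, classes=None) -> "ConfusionMatrix":
        true = np.asarray(true)
        predicted = np.asarray(predicted)
        if true.shape != predicted.shape:
            raise DataError("true/predicted length mismatch")
        if classes is None:
            classes = tuple(sorted(np.unique(np.concatenate([true, predicted]))))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(true, predicted):
            counts[index[t], index[p]] += 1
        return cls(tuple(classes), counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean per-class recall (diagonal over row sum)."""
    rows = cm.counts.sum(axis=1)
    if (rows == 0).any():
        raise DataError("every true class must appear at least once")
    return float(np.mean(np.diag(cm.counts) / rows))


def f1(cm: ConfusionMatrix, positive_class: str) -> float:
    """Harmonic mean of precision and recall for one positive class.

    Defined as 0 when precision + recall degenerates to 0.
    """
    if positive_class not in cm.classes:
        raise DataError(f"class {positive_class!r} not in confusion matrix")
    i = cm.classes.index(positive_class)
    tp = cm.counts[i, i]
    fp = cm.counts[:, i].sum() - tp
    fn = cm.counts[i, :].sum() - tp
    if 2 * tp + fp + fn == 0:
        return 0.0
    return float(2 * tp / (2 * tp + fp + fn))


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of the per-class one-vs-rest F1 scores."""
    return float(np.mean([f1(cm, c) for c in cm.classes]))


@dataclass
class EvalReport:
    """Metrics bundle for one fitted model on one test set."""

    confusion: ConfusionMatrix
    balanced_accuracy: float
    f1: float                      # binary F1 or macro-F1 for ternary
    kfold_loss: float | None = None
    meta: dict = field(default_factory=dict)


def evaluate_predictions(true, predicted, positive_class: str | None = None,
                         classes=None) -> EvalReport:
    """Confusion matrix + balanced accuracy + (macro-)F1 for predictions."""
    cm = ConfusionMatrix.from_labels(true, predicted, classes)
    score = f1(cm, positive_class) if positive_class else macro_f1(cm)
    return EvalReport(cm, balanced_accuracy(cm), score)


def split_train_test(labels, train_frac: float = 0.8, seed: int = 0,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random train/test index split.

    Within each class, round(train_frac * n_c) samples go to training, so
    class proportions are preserved to within one sample per class.
    """
    if not 0.0 < train_frac < 1.0:
        raise DataError("train_frac must lie in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        if idx.size < 2:
            raise DataError(f"class {c!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def kfold_indices(labels, k: int, seed: int = 0) -> list[np.ndarray]:
    """Stratified fold assignment: disjoint, exhaustive, seeded."""
    labels = np.asarray(labels)
    if not 2 <= k <= labels.size:
        raise DataError(f"k must lie in [2, {labels.size}], got {k}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    # Round-robin with a cursor carried across classes: folds stay within
    # one sample of each other in size and in per-class composition, and
    # k = n degenerates to leave-one-out.
    cursor = 0
    for c in np.unique(labels):
        idx = rng.permutation(np.nonzero(labels == c)[0])
        for sample in idx:
            folds[cursor % k].append(int(sample))
            cursor += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def kfold_loss(X, labels, trainer, k: int = 10, seed: int = 0) -> float:
    """Mean held-out misclassification fraction over stratified folds.

    ``trainer(X_train, y_train)`` must return a ``predict(X) -> labels``
    callable. ``X`` may be any object indexable by an integer array (a 2-D
    numpy array, or a list wrapped via ``np.asarray(..., dtype=object)``).
    """
    labels = np.asarray(labels)
    X = np.asarray(X) if not isinstance(X, np.ndarray) else X
    losses = []
    for fold in kfold_indices(labels, k, seed):
        mask = np.ones(labels.size, dtype=bool)
        mask[fold] = False
        train_idx = np.nonzero(mask)[0]
        model_predict = trainer(X[train_idx], labels[train_idx])
        predicted = np.asarray(model_predict(X[fold]))
        losses.append(float(np.mean(predicted != labels[fold])))
    return float(np.mean(losses))
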