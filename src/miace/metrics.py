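"""Evaluation metrics: confusion matrices, rank-1 accuracy, cross entropy,
one-vs-rest per-class scores, and epsilon-softening of crisp probabilities.

Rank-1 accuracy is the fraction of crowns whose true class receives the
highest assigned probability; cross entropy is the mean negative log
probability assigned to the true class. Crisp 0/1 probabilities give an
infinite cross entropy whenever a single crown is misclassified, so crisp
outputs can be *softened*: the predicted class is assigned
``1 - (C-1)*eps`` and every other class ``eps``. For a classifier at
rank-1 accuracy ``a`` the softened cross entropy

    c(eps) = -[ a*ln(1 - (C-1)*eps) + (1-a)*ln(eps) ]

is convex on ``0 < eps < 1/(C-1)`` with closed-form minimizer
``eps* = (1-a)/(C-1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .ovo import BagPrediction, PredictionSet

__all__ = [
    "ConfusionMatrix",
    "SofteningScheme",
    "confusion",
    "rank1_accuracy",
    "cross_entropy",
    "per_class_metrics",
    "soften",
    "optimal_epsilon",
    "softened_cross_entropy",
]


@dataclass(frozen=True, eq=False)
class ConfusionMatrix:
    """Counts with rows = ground truth, columns = prediction.

    Counts are integer-valued for a single evaluation; fold-averaged
    matrices (cross validation) carry fractional counts.
    """

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.counts, dtype=float)
        C = len(self.classes)
        if m.shape != (C, C):
            raise ValueError(f"counts must be {C}x{C}")
        if np.any(m < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", m)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Overall (rank-1, for crisp predictions) accuracy: trace / total."""
        return float(np.trace(self.counts) / self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConfusionMatrix":
        return cls(tuple(frame.index), frame.to_numpy(dtype=float))


def confusion(preds: PredictionSet) -> ConfusionMatrix:
    """Tally a confusion matrix from predictions with ground truth."""
    classes = preds.classes
    index = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)))
    for p in preds:
        if p.truth is None:
            raise ValueError(f"bag {p.bag_id!r} has no ground truth")
        if p.truth not in index:
            raise ValueError(f"bag {p.bag_id!r} truth {p.truth!r} outside class vocabulary")
        if p.predicted not in index:
            raise ValueError(f"bag {p.bag_id!r} prediction {p.predicted!r} outside vocabulary")
        m[index[p.truth], index[p.predicted]] += 1
    return ConfusionMatrix(classes, m)


def rank1_accuracy(preds: PredictionSet) -> float:
    """Fraction of bags whose true class has the highest probability.

    For crisp predictions this equals trace/total of the confusion matrix.
    A probability argmax tie is resolved in favour of the recorded
    predicted label when it participates in the tie (mirroring the voting
    tie resolution that produced it), and is flagged with a warning.
    """
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    classes = preds.classes
    P = preds.probability_matrix()
    truths = preds.truth_labels()
    correct = 0
    n_ties = 0
    for row, p, truth in zip(P, preds, truths):
        top = row.max()
        tied = [classes[i] for i in np.flatnonzero(row == top)]
        if len(tied) > 1:
            n_ties += 1
            label = p.predicted if p.predicted in tied else tied[0]
        else:
            label = tied[0]
        correct += label == truth
    if n_ties:
        warnings.warn(f"{n_ties} bag(s) had tied argmax probabilities", stacklevel=2)
    return correct / len(preds)


def cross_entropy(preds: PredictionSet) -> float:
    """Mean negative log probability of the true class.

    Any bag assigning probability 0 to its true class is a hard error
    (apply :func:`soften` first to make the value finite).
    """
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    total = 0.0
    for p in preds:
        if p.truth is None:
            raise ValueError(f"bag {p.bag_id!r} has no ground truth")
        p_true = p.probabilities.get(p.truth, 0.0)
        if p_true <= 0.0:
            raise ValueError(
                f"bag {p.bag_id!r} assigns probability 0 to its true class "
                f"{p.truth!r}; cross entropy is infinite (epsilon-soften first)"
            )
        total -= np.log(p_true)
    return total / len(preds)


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest accuracy, specificity, precision, recall, and F1 per class.

    A class never predicted (TP+FP = 0) has undefined precision, reported
    as 0 with ``precision_defined=False``; likewise for recall (no true
    bags) and F1 (precision + recall = 0).
    """
    m = cm.counts
    total = m.sum()
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = total - tp - fp - fn

    with np.errstate(invalid="ignore", divide="ignore"):
        accuracy = (tp + tn) / total
        specificity = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
        precision_defined = tp + fp > 0
        precision = np.where(precision_defined, tp / np.where(precision_defined, tp + fp, 1), 0.0)
        recall_defined = tp + fn > 0
        recall = np.where(recall_defined, tp / np.where(recall_defined, tp + fn, 1), 0.0)
        f1_defined = precision + recall > 0
        f1 = np.where(f1_defined, 2 * precision * recall / np.where(f1_defined, precision + recall, 1), 0.0)
    return pd.DataFrame(
        {
            "accuracy": accuracy,
            "specificity": specificity,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "precision_defined": precision_defined,
            "recall_defined": recall_defined,
            "f1_defined": f1_defined,
        },
        index=list(cm.classes),
    )


@dataclass(frozen=True)
class SofteningScheme:
    """Replace crisp probabilities with eps / 1-(C-1)*eps."""

    epsilon: float
    n_classes: int

    def __post_init__(self) -> None:
        C = self.n_classes
        if C < 2:
            raise ValueError("softening needs at least 2 classes")
        if not 0.0 <= self.epsilon < 1.0 / (C - 1):
            raise ValueError(f"epsilon must lie in [0, 1/(C-1)) = [0, {1.0/(C-1):.4g})")

    @property
    def top_probability(self) -> float:
        return 1.0 - (self.n_classes - 1) * self.epsilon


def soften(preds: PredictionSet, scheme: SofteningScheme) -> PredictionSet:
    """Apply epsilon-softening to crisp predictions; rows still sum to 1."""
    if scheme.n_classes != len(preds.classes):
        raise ValueError(
            f"scheme is for {scheme.n_classes} classes, predictions have {len(preds.classes)}"
        )
    if scheme.epsilon == 0.0:
        return preds
    for p in preds:
        if not all(v in (0.0, 1.0) for v in p.probabilities.values()):
            raise ValueError(f"bag {p.bag_id!r} probabilities are not crisp 0/1")
    softened = [
        replace(
            p,
            probabilities={
                c: scheme.top_probability if c == p.predicted else scheme.epsilon
                for c in preds.classes
            },
        )
        for p in preds.predictions
    ]
    return PredictionSet(classes=preds.classes, predictions=softened, level=preds.level)


def softened_cross_entropy(accuracy: float, n_classes: int, epsilon: float) -> float:
    """Closed-form mean cross entropy of softened crisp predictions at a
    given rank-1 accuracy: -[a*ln(1-(C-1)*eps) + (1-a)*ln(eps)]."""
    scheme = SofteningScheme(epsilon, n_classes)  # validates the range
    a = float(accuracy)
    if not 0.0 <= a <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    terms = 0.0
    if a > 0:
        terms += a * np.log(scheme.top_probability)
    if a < 1:
        if epsilon == 0.0:
            return float("inf")
        terms += (1.0 - a) * np.log(epsilon)
    return float(-terms)


def optimal_epsilon(accuracy: float, n_classes: int) -> float:
    """Epsilon minimizing the softened cross entropy: (1-a)/(C-1).

    ``accuracy=1`` returns 0 (no softening needed); ``accuracy=0`` returns
    the upper bound of the valid range with a warning (the cross entropy
    decreases monotonically toward it).
    """
    a = float(accuracy)
    C = int(n_classes)
    if C < 2:
        raise ValueError("need at least 2 classes")
    if not 0.0 <= a <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if a == 1.0:
        return 0.0
    if a == 0.0:
        warnings.warn(
            "accuracy 0: softened cross entropy has no interior minimum; "
            "returning the upper bound of the valid epsilon range",
            stacklevel=2,
        )
        return 1.0 / (C - 1)
    return (1.0 - a) / (C - 1)
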