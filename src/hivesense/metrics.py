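"""Evaluation metrics: categorical cross-entropy, confusion-matrix accuracy,
and the convergence-speed rate used to judge training health.

Convergence speed over epochs k..n is the mean per-epoch accuracy gain

    Conv = sum_{i=k}^{n-1} (Acc_{i+1} - Acc_i) / (n - k + 1)
         = (Acc_n - Acc_k) / (n - k + 1)

with accuracies in percentage points.  Interpretation: values well above 1
mean fast gains (watch for overfitting); values in (0, 1] a healthy curve;
values near 0 a plateau; values well below -1 an underachieving model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError, ShapeError

#: Floor applied to predicted probabilities before taking logs.
PROB_FLOOR = 1e-12

#: Epochs at which convergence speed is conventionally reported.
DEFAULT_BREAKPOINTS = (20, 50, 100)


def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean categorical cross-entropy between target and predicted distributions.

    ``y_true`` may be one-hot or label-smoothed class vectors; ``y_pred``
    holds per-class probabilities.  Predictions are clipped to ``PROB_FLOOR``
    before the log to avoid infinities.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=np.float64))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=np.float64))
    if y_true.shape != y_pred.shape:
        raise ShapeError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    logs = np.log(np.clip(y_pred, PROB_FLOOR, None))
    return float(-(y_true * logs).sum(axis=1).mean())


@dataclass
class ConfusionMatrix:
    """Counts with rows = actual class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ShapeError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise InputError("confusion matrix counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> "ConfusionMatrix":
        counts = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(counts, (np.asarray(y_true, dtype=np.int64), np.asarray(y_pred, dtype=np.int64)), 1)
        return cls(counts=counts)


def accuracy(cm: ConfusionMatrix | np.ndarray) -> float:
    """Diagonal sum over total count: the fraction of correctly detected samples."""
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else ConfusionMatrix(np.asarray(cm)).counts
    total = counts.sum()
    if total == 0:
        raise InputError("confusion matrix is empty")
    return float(np.trace(counts) / total)


@dataclass
class EpochMetrics:
    """Per-epoch validation accuracy (percent) and loss series."""

    accuracy: np.ndarray
    loss: np.ndarray
    epochs: np.ndarray | None = None
    breakpoints: tuple[int, ...] = DEFAULT_BREAKPOINTS

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=np.float64)
        self.loss = np.asarray(self.loss, dtype=np.float64)
        if self.epochs is None:
            self.epochs = np.arange(1, len(self.accuracy) + 1)
        self.epochs = np.asarray(self.epochs, dtype=np.int64)
        if not (len(self.accuracy) == len(self.loss) == len(self.epochs)):
            raise ShapeError("accuracy, loss, and epoch series must align")
        if len(self.epochs) and np.any(np.diff(self.epochs) <= 0):
            raise InputError("epoch indices must be strictly increasing")
        if np.any((self.accuracy < 0) | (self.accuracy > 100)):
            raise InputError("accuracies must be percentages in [0, 100]")

    def _acc_at(self, epoch: int) -> float:
        pos = np.searchsorted(self.epochs, epoch)
        if pos >= len(self.epochs) or self.epochs[pos] != epoch:
            raise ParameterError(f"epoch {epoch} is not in the recorded series")
        return float(self.accuracy[pos])

    def summary(self) -> dict:
        """Accuracy and convergence speed at each breakpoint present in the series.

        The rate at breakpoint ``n`` is taken from the previous breakpoint (or
        the first recorded epoch) to ``n``.
        """
        out = {}
        prev = int(self.epochs[0])
        for bp in self.breakpoints:
            if bp > int(self.epochs[-1]):
                break
            out[bp] = {
                "accuracy": self._acc_at(bp),
                "convergence_speed": convergence_speed(self, k=prev, n=bp),
            }
            prev = bp
        return out


def convergence_speed(metrics: EpochMetrics, k: int, n: int) -> float:
    """Mean per-epoch accuracy gain between epochs ``k`` and ``n``.

    Telescopes to (Acc_n - Acc_k) / (n - k + 1); both forms are identical
    for any series.
    """
    if k >= n:
        raise ParameterError(f"need k < n, got k={k}, n={n}")
    acc_k = metrics._acc_at(k)
    acc_n = metrics._acc_at(n)
    return (acc_n - acc_k) / (n - k + 1)


def interpret_convergence(value: float, plateau_eps: float = 0.05) -> str:
    """Qualitative band for a convergence-speed value."""
    if abs(value) <= plateau_eps:
        return "plateau"
    if value > 1.0:
        return "fast (possible overfit)"
    if value > 0.0:
        return "improving"
    if value >= -1.0:
        return "declining"
    return "underachieving"
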