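"""Binary-classification metrics at the 0.5 decision threshold.

The positive class is "disease present" (target 1).  AUC is the Mann-Whitney
pair statistic — the probability a random positive scores above a random
negative, with half credit for ties — computed from midranks.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the derived rates for one evaluation set."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def error_rate(self) -> float:
        return (self.fp + self.fn) / self.n if self.n else 0.0

    def to_dict(self) -> dict:
        return asdict(self) | {"n": self.n, "error_rate": self.error_rate}


def confusion_counts(y: np.ndarray, labels: np.ndarray) -> tuple[int, int, int, int]:
    y = np.asarray(y).astype(int)
    labels = np.asarray(labels).astype(int)
    if y.shape != labels.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {labels.shape}")
    tp = int(np.sum((y == 1) & (labels == 1)))
    fp = int(np.sum((y == 0) & (labels == 1)))
    tn = int(np.sum((y == 0) & (labels == 0)))
    fn = int(np.sum((y == 1) & (labels == 0)))
    return tp, fp, tn, fn


def _safe(num: float, den: float) -> float:
    return num / den if den else 0.0


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC from midranks; ties get half credit."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def evaluate_predictions(y: np.ndarray, scores: np.ndarray,
                         threshold: float = 0.5) -> MetricsReport:
    """Full metric set from probabilities; errors on an empty set."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(y) == 0:
        raise ValueError("cannot evaluate an empty test set")
    labels = (scores >= threshold).astype(int)
    tp, fp, tn, fn = confusion_counts(y, labels)
    precision = _safe(tp, tp + fp)
    recall = _safe(tp, tp + fn)
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=_safe(tp + tn, len(y)),
        precision=precision,
        recall=recall,
        specificity=_safe(tn, tn + fp),
        f1=_safe(2 * precision * recall, precision + recall),
        auc=auc(scores, y) if 0 < y.sum() < len(y) else float("nan"),
    )


def roc_coordinates(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(fpr, tpr, threshold) rows over all score cut points, for CSV export."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    n1, n0 = ys.sum(), len(ys) - ys.sum()
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    rows = [(0.0, 0.0, np.inf)]
    for i in range(len(ys)):
        if i == len(ys) - 1 or scores[order][i] != scores[order][i + 1]:
            rows.append((fps[i] / max(n0, 1), tps[i] / max(n1, 1), scores[order][i]))
    return np.array(rows)
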