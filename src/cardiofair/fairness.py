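"""Demographic inverse-frequency reweighting and subgroup fairness reporting.

Each training sample gets weight ``w_i = 1 / p(g_i)`` where ``p(g)`` is its
demographic group's proportion in the training fold, upweighting minorities.
Raw inverse-frequency weights are rescaled so the per-sample mean is 1
(equivalently sum(w) = n): the raw sum would otherwise change the effective
learning rate with group imbalance, confounding the fairness effect.

The fairness report follows the subgroup protocol on two axes — gender
(male/female) and the age-50 split: per cross-validation fold, subgroup F1
and error rates are computed on the test fold; the per-axis gap is the
absolute subgroup difference in that fold; the final gap is the mean over
folds.  Folds where a subgroup has no test samples are excluded for that
axis and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Tensor, clip, log

__all__ = ["GroupWeightTable", "FairnessReport", "group_proportions",
           "inverse_frequency_weights", "sample_weights", "reweighted_bce",
           "subgroup_metrics", "fairness_report", "AXES"]

#: fairness axes and the subgroup key prefix/suffix that defines each side
AXES = {
    "gender": (("male", "female"), lambda key: key.split(":")[0]),
    "age": (("lt50", "ge50"), lambda key: key.split(":")[1]),
}

EPS = 1e-7


@dataclass(frozen=True)
class GroupWeightTable:
    """p(g), raw w(g) = 1/p(g), and the mean-1 normalization."""

    proportions: dict[str, float]
    raw_weights: dict[str, float]
    weights: dict[str, float]
    normalization: float

    def weight_for(self, group: str) -> float:
        return self.weights[group]


def group_proportions(keys) -> dict[str, float]:
    """Group proportions; they sum to 1 by construction."""
    keys = list(keys)
    if not keys:
        raise ValueError("cannot compute proportions of an empty cohort")
    counts = pd.Series(keys).value_counts()
    return {g: float(c) / len(keys) for g, c in counts.items()}


def inverse_frequency_weights(proportions: dict[str, float]) -> GroupWeightTable:
    """w(g) = 1/p(g), rescaled so the dataset-mean per-sample weight is 1."""
    for g, p in proportions.items():
        if p <= 0:
            raise ValueError(f"group {g!r} absent from the training fold (p=0)")
    raw = {g: 1.0 / p for g, p in proportions.items()}
    # mean per-sample raw weight = sum_g p(g) * (1/p(g)) = number of groups
    mean_raw = sum(proportions[g] * raw[g] for g in raw)
    weights = {g: w / mean_raw for g, w in raw.items()}
    return GroupWeightTable(proportions=dict(proportions), raw_weights=raw,
                            weights=weights, normalization=mean_raw)


def sample_weights(keys, table: GroupWeightTable | None = None) -> np.ndarray:
    """Per-sample weight vector; uniform 1s when no table is given."""
    keys = list(keys)
    if table is None:
        return np.ones(len(keys))
    return np.array([table.weight_for(k) for k in keys])


def reweighted_bce(y, yhat, w):
    """Fairness-aware loss: ``-sum_i w_i [y_i log yhat_i + (1-y_i) log(1-yhat_i)]``.

    Probabilities are clamped to [EPS, 1-EPS].  With all weights 1 this is
    the ordinary summed binary cross-entropy.  Accepts autodiff tensors for
    ``yhat`` (training) or plain arrays (reporting).
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if isinstance(yhat, Tensor):
        if yhat.data.shape != y.shape or y.shape != w.shape:
            raise ValueError("length mismatch between labels, predictions and weights")
    elif np.asarray(yhat).shape != y.shape or y.shape != w.shape:
        raise ValueError("length mismatch between labels, predictions and weights")
    p = clip(yhat, EPS, 1.0 - EPS)
    ll = y * log(p) + (1.0 - y) * log(1.0 - p)
    return -(w * ll).sum()


def subgroup_metrics(y, scores, keys, threshold: float = 0.5) -> dict[str, dict]:
    """F1 and error rate per demographic subgroup on one evaluation set."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    keys = np.asarray(list(keys))
    out: dict[str, dict] = {}
    for axis, (sides, keyfn) in AXES.items():
        side_of = np.array([keyfn(k) for k in keys])
        for side in sides:
            mask = side_of == side
            if not mask.any():
                out[f"{axis}:{side}"] = {"n": 0, "f1": None, "error_rate": None}
                continue
            labels = (scores[mask] >= threshold).astype(int)
            ys = y[mask]
            tp = int(np.sum((ys == 1) & (labels == 1)))
            fp = int(np.sum((ys == 0) & (labels == 1)))
            fn = int(np.sum((ys == 1) & (labels == 0)))
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            out[f"{axis}:{side}"] = {
                "n": int(mask.sum()), "f1": f1,
                "error_rate": float(np.mean(labels != ys)),
            }
    return out


@dataclass
class FairnessReport:
    """Per-axis fairness gaps: mean over folds of |subgroup difference|."""

    delta_f1: dict[str, float]
    delta_error: dict[str, float]
    per_fold: list[dict]
    excluded_folds: dict[str, list[int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"delta_f1": self.delta_f1, "delta_error": self.delta_error,
                "per_fold": self.per_fold, "excluded_folds": self.excluded_folds}

    def as_table(self, scale: float = 1.0) -> str:
        """Text table mirroring the subgroup / gap layout of the protocol."""
        lines = [f"{'Subgroup':<16}{'F1':>10}{'Error rate':>14}"]
        means: dict[str, list] = {}
        for fold in self.per_fold:
            for key, m in fold["subgroups"].items():
                if m["f1"] is not None:
                    means.setdefault(key, []).append((m["f1"], m["error_rate"]))
        for key, vals in means.items():
            f1 = np.mean([v[0] for v in vals]) * scale
            er = np.mean([v[1] for v in vals]) * scale
            lines.append(f"{key:<16}{f1:>10.2f}{er:>14.2f}")
        for axis in self.delta_f1:
            lines.append(f"{'dF1(' + axis + ')':<16}{self.delta_f1[axis] * scale:>10.2f}"
                         f"{self.delta_error[axis] * scale:>14.2f}")
        return "\n".join(lines)


def fairness_report(per_fold_subgroup_metrics: list[dict[str, dict]]) -> FairnessReport:
    """Aggregate per-fold subgroup metrics into the final fairness gaps.

    Each element maps subgroup keys (``gender:male`` etc.) to ``f1`` and
    ``error_rate``; a fold missing one side of an axis is excluded from that
    axis's mean and recorded in ``excluded_folds``.
    """
    delta_f1: dict[str, list[float]] = {a: [] for a in AXES}
    delta_err: dict[str, list[float]] = {a: [] for a in AXES}
    excluded: dict[str, list[int]] = {a: [] for a in AXES}
    per_fold = []
    for i, sub in enumerate(per_fold_subgroup_metrics):
        fold_entry = {"fold": i, "subgroups": sub, "gaps": {}}
        for axis, (sides, _) in AXES.items():
            a, b = (sub.get(f"{axis}:{s}") for s in sides)
            if not a or not b or a["f1"] is None or b["f1"] is None:
                excluded[axis].append(i)
                continue
            gap_f1 = abs(a["f1"] - b["f1"])
            gap_er = abs(a["error_rate"] - b["error_rate"])
            delta_f1[axis].append(gap_f1)
            delta_err[axis].append(gap_er)
            fold_entry["gaps"][axis] = {"delta_f1": gap_f1, "delta_error": gap_er}
        per_fold.append(fold_entry)
    return FairnessReport(
        delta_f1={a: float(np.mean(v)) if v else float("nan") for a, v in delta_f1.items()},
        delta_error={a: float(np.mean(v)) if v else float("nan") for a, v in delta_err.items()},
        per_fold=per_fold,
        excluded_folds={a: v for a, v in excluded.items() if v},
    )
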