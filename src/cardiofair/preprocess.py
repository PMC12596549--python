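"""Encoding clinical records into a model-ready design matrix, plus
stratified cross-validation folds.

Continuous features are min-max scaled to [0, 1] with statistics fitted on the
training partition only; values seen at transform time outside the fitted
range are clipped back into [0, 1].  Multi-level categoricals are one-hot
encoded over their declared domains in fixed schema order, so the column
layout (and therefore checkpoints and attributions) is reproducible:
5 numeric + 3 binary + one-hot blocks for cp(4), restecg(3), slope(3),
ca(4), thal(3) = 25 columns.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler

from .schema import (BINARY, CATEGORICAL_DOMAINS, NUMERIC, PREDICTORS,
                     Cohort, SchemaError)

__all__ = ["EncodedMatrix", "Encoder", "FoldPlan", "make_folds", "count_missing",
           "encoded_feature_names", "FEATURE_BLOCKS"]

#: encoded-column block per original predictor, in schema order
FEATURE_BLOCKS: dict[str, list[str]] = {}
for _name in PREDICTORS:
    if _name in CATEGORICAL_DOMAINS:
        FEATURE_BLOCKS[_name] = [f"{_name}={c}" for c in CATEGORICAL_DOMAINS[_name]]
    else:
        FEATURE_BLOCKS[_name] = [_name]


def encoded_feature_names() -> list[str]:
    """The 25 encoded column labels in canonical order."""
    return [col for name in PREDICTORS for col in FEATURE_BLOCKS[name]]


@dataclass
class EncodedMatrix:
    """A normalized, one-hot design matrix plus the metadata to rebuild it."""

    values: np.ndarray
    feature_names: list[str]
    scaling: dict[str, tuple[float, float]]          # numeric feature -> (Xmin, Xmax)
    encoding_map: dict[str, dict[int, int]]          # categorical -> {code: column index}
    y: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def metadata_json(self) -> str:
        return json.dumps({
            "feature_names": self.feature_names,
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "encoding_map": {k: {str(c): i for c, i in v.items()}
                             for k, v in self.encoding_map.items()},
        }, indent=2)


class Encoder:
    """Fits min-max scaling on a training cohort; transforms any cohort.

    The transform refuses missing predictors (impute first) and categorical
    codes outside the declared domains.
    """

    def __init__(self):
        self._scaler: MinMaxScaler | None = None
        self.scaling_: dict[str, tuple[float, float]] = {}
        self.fitted_on_n_: int | None = None
        self.fit_fingerprint_: int | None = None

    def fit(self, cohort: Cohort) -> "Encoder":
        if cohort.n == 0:
            raise SchemaError("cannot fit an encoder on an empty cohort")
        X = cohort.df[list(NUMERIC)].to_numpy()
        if np.isnan(X).any():
            raise SchemaError("numeric predictors must be complete before encoding")
        self._scaler = MinMaxScaler(clip=True).fit(X)
        self.scaling_ = {name: (float(lo), float(hi))
                         for name, lo, hi in zip(NUMERIC, self._scaler.data_min_,
                                                 self._scaler.data_max_)}
        self.fitted_on_n_ = cohort.n
        self.fit_fingerprint_ = zlib.crc32(X.tobytes())
        return self

    def transform(self, cohort: Cohort) -> EncodedMatrix:
        if self._scaler is None:
            raise RuntimeError("Encoder.transform called before fit")
        df = cohort.df
        if df[list(PREDICTORS)].isna().any().any():
            bad = [c for c in PREDICTORS if df[c].isna().any()]
            raise SchemaError(f"missing values remain in {bad}; impute before encoding")
        n = cohort.n
        names = encoded_feature_names()
        out = np.zeros((n, len(names)))
        scaled = self._scaler.transform(df[list(NUMERIC)].to_numpy()) if n else \
            np.zeros((0, len(NUMERIC)))
        encoding_map: dict[str, dict[int, int]] = {}
        col = 0
        for name in PREDICTORS:
            if name in NUMERIC:
                out[:, col] = scaled[:, NUMERIC.index(name)]
                col += 1
            elif name in BINARY:
                out[:, col] = df[name].to_numpy()
                col += 1
            else:
                domain = CATEGORICAL_DOMAINS[name]
                encoding_map[name] = {}
                codes = df[name].to_numpy()
                bad = ~np.isin(codes, list(map(float, domain)))
                if bad.any():
                    raise SchemaError(f"unseen {name!r} categories at transform time: "
                                      f"{sorted(set(codes[bad]))}")
                for c in domain:
                    out[:, col] = (codes == float(c)).astype(float)
                    encoding_map[name][c] = col
                    col += 1
        return EncodedMatrix(values=out, feature_names=names,
                             scaling=dict(self.scaling_), encoding_map=encoding_map,
                             y=df["target"].to_numpy().astype(float))

    def fit_transform(self, cohort: Cohort) -> EncodedMatrix:
        return self.fit(cohort).transform(cohort)

    def decode_categorical(self, matrix: EncodedMatrix, name: str) -> np.ndarray:
        """Recover the original categorical codes from a one-hot block."""
        if name not in matrix.encoding_map:
            raise SchemaError(f"{name!r} is not an encoded categorical")
        block = matrix.encoding_map[name]
        codes = np.array(list(block.keys()), dtype=float)
        cols = matrix.values[:, list(block.values())]
        return codes[np.argmax(cols, axis=1)]


def transform_minmax(x, scaling: tuple[float, float]):
    """Scale `x` by a fitted (Xmin, Xmax) pair, clipping to [0, 1].

    A constant training column (Xmax == Xmin) maps everything to 0.
    """
    lo, hi = scaling
    if hi == lo:
        return np.zeros_like(np.asarray(x, dtype=float)) if np.ndim(x) else 0.0
    return np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def count_missing(cohort: Cohort, column: str) -> int:
    """Records with `column` explicitly flagged missing."""
    return cohort.count_missing(column)


@dataclass
class FoldPlan:
    """A k-fold partition: ``assignments[i]`` is record i's test fold."""

    k: int
    assignments: np.ndarray
    seed: int
    stratified: bool = True

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "k": self.k, "seed": self.seed, "stratified": self.stratified,
            "assignments": self.assignments.tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        d = json.loads(Path(path).read_text())
        return cls(k=d["k"], assignments=np.array(d["assignments"], dtype=int),
                   seed=d["seed"], stratified=d["stratified"])


def make_folds(cohort: Cohort, k: int, seed: int) -> FoldPlan:
    """Stratified k-fold assignment preserving the class balance per fold."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > cohort.n:
        raise ValueError(f"k={k} exceeds cohort size n={cohort.n}")
    y = cohort.df["target"].to_numpy().astype(int)
    assignments = np.empty(cohort.n, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(cohort.n), y)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed, stratified=True)
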