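"""Clinical feature schema for the 14-field heart-disease record layout.

The layout follows the widely used "processed" dialect of the UCI Heart
Disease data: 13 predictors plus a binary target.  Missing values are carried
as ``NaN`` in the in-memory table and as ``?`` on disk — never as sentinel
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Predictor columns in canonical (on-disk) order.
PREDICTORS: tuple[str, ...] = (
    "age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
    "thalach", "exang", "oldpeak", "slope", "ca", "thal",
)
TARGET = "target"
COLUMNS: tuple[str, ...] = PREDICTORS + (TARGET,)

#: Continuous predictors, min-max normalized before modelling.
NUMERIC: tuple[str, ...] = ("age", "trestbps", "chol", "thalach", "oldpeak")
#: 0/1 predictors passed through as single columns.
BINARY: tuple[str, ...] = ("sex", "fbs", "exang")
#: Multi-level categoricals and their admissible codes (one-hot encoded).
CATEGORICAL_DOMAINS: dict[str, tuple[int, ...]] = {
    "cp": (1, 2, 3, 4),
    "restecg": (0, 1, 2),
    "slope": (1, 2, 3),
    "ca": (0, 1, 2, 3),
    "thal": (3, 6, 7),
}

#: Plausible ranges for continuous predictors (used by the simulator and for
#: light validation; real cohorts occasionally exceed these, so validation of
#: numerics only requires finiteness and the documented sign constraints).
NUMERIC_RANGES: dict[str, tuple[float, float]] = {
    "age": (29.0, 77.0),
    "trestbps": (90.0, 200.0),
    "chol": (120.0, 570.0),
    "thalach": (70.0, 210.0),
    "oldpeak": (0.0, 6.2),
}

#: Age threshold splitting the two age subgroups used in fairness reporting.
AGE_SPLIT = 50.0


class SchemaError(ValueError):
    """A record or table violates the clinical schema."""


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's predictors plus the binary outcome.

    ``None`` marks an explicitly missing predictor value.
    """

    age: float
    sex: int
    cp: int | None
    trestbps: float
    chol: float
    fbs: int
    restecg: int | None
    thalach: float
    exang: int
    oldpeak: float
    slope: int | None
    ca: int | None
    thal: int | None
    target: int

    def __post_init__(self):
        for name in NUMERIC:
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise SchemaError(f"{name} must be finite, got {v!r}")
        if self.oldpeak is not None and self.oldpeak < 0:
            raise SchemaError(f"oldpeak must be >= 0, got {self.oldpeak}")
        for name in BINARY:
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise SchemaError(f"{name} must be 0/1, got {v!r}")
        for name, domain in CATEGORICAL_DOMAINS.items():
            v = getattr(self, name)
            if v is not None and v not in domain:
                raise SchemaError(f"{name}={v!r} outside domain {domain}")
        if self.target not in (0, 1):
            raise SchemaError(f"target must be 0/1, got {self.target!r}")


@dataclass
class Cohort:
    """A table of clinical records (rows) in schema column order.

    Missing predictor values are ``NaN``; the target is never missing.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.df = validate_table(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def count_missing(self, column: str) -> int:
        """Number of records with `column` flagged missing."""
        if column not in COLUMNS:
            raise SchemaError(f"unknown field {column!r}")
        return int(self.df[column].isna().sum())

    def records(self) -> list[ClinicalRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            kw = {}
            for name in COLUMNS:
                v = getattr(row, name)
                if isinstance(v, float) and np.isnan(v):
                    kw[name] = None
                elif name in NUMERIC:
                    kw[name] = float(v)
                else:
                    kw[name] = int(v)
            out.append(ClinicalRecord(**kw))
        return out

    def group_keys(self) -> pd.Series:
        """Demographic key per record: sex crossed with the age-50 split."""
        sex = np.where(self.df["sex"].to_numpy() == 1, "male", "female")
        age = np.where(self.df["age"].to_numpy() < AGE_SPLIT, "lt50", "ge50")
        return pd.Series([f"{s}:{a}" for s, a in zip(sex, age)], index=self.df.index)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy())


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a cohort table; returns a float64 copy."""
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing columns: {missing_cols}")
    df = df.loc[:, list(COLUMNS)].astype(np.float64).reset_index(drop=True)
    if len(df) == 0:
        return df
    if df[TARGET].isna().any():
        raise SchemaError("target may not be missing")
    bad_target = ~df[TARGET].isin([0.0, 1.0])
    if bad_target.any():
        raise SchemaError(f"target must be 0/1; offending rows {list(df.index[bad_target])[:5]}")
    for name, domain in CATEGORICAL_DOMAINS.items():
        col = df[name]
        bad = col.notna() & ~col.isin(list(map(float, domain)))
        if bad.any():
            raise SchemaError(
                f"field {name!r} outside domain {domain} in rows {list(df.index[bad])[:5]}")
    for name in BINARY:
        col = df[name]
        bad = col.notna() & ~col.isin([0.0, 1.0])
        if bad.any():
            raise SchemaError(f"field {name!r} must be 0/1 in rows {list(df.index[bad])[:5]}")
    for name in NUMERIC:
        col = df[name].to_numpy()
        observed = ~np.isnan(col)
        if not np.isfinite(col[observed]).all():
            raise SchemaError(f"field {name!r} has non-finite values")
    op = df["oldpeak"]
    if (op.notna() & (op < 0)).any():
        raise SchemaError("oldpeak must be >= 0")
    return df
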