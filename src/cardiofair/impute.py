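"""Fuzzy-membership-weighted multiple imputation for clinical records.

Each missing cell is filled from donor records that observe the field.  Donor
similarity is a Gaussian kernel of the normalized Euclidean distance over
co-observed features (min-max-scaled numerics, simple-matching categoricals),
so membership decays smoothly with distance.  "Multiple" imputation draws
``m`` seeded donor subsets; numeric cells take the mean of the
membership-weighted subset means, categorical cells the category with the
highest total membership across draws.  Imputed values therefore always lie
inside the observed value set of the field.

Within cross-validation the imputer is fitted on the training partition only
(its donors and distance scaling never see the test fold) and then applied
unchanged to the test partition.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import COLUMNS, NUMERIC, PREDICTORS, Cohort, SchemaError

__all__ = ["ImputationConfig", "ImputationError", "ImputationReport",
           "FuzzyImputer", "membership_weights", "fuzzy_impute",
           "imputation_report"]


class ImputationError(ValueError):
    """A missing field cannot be imputed (no complete donors)."""


@dataclass(frozen=True)
class ImputationConfig:
    m: int = 5                      # number of imputation draws
    kernel_bandwidth: float = 0.5   # sigma of the Gaussian membership kernel
    k_donors: int = 20              # donors sampled per draw
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.k_donors < 1:
            raise ValueError(f"k_donors must be >= 1, got {self.k_donors}")
        if self.kernel_bandwidth <= 0:
            raise ValueError(f"kernel_bandwidth must be > 0, got {self.kernel_bandwidth}")


@dataclass
class ImputationReport:
    """Distributional stability diagnostics: observed-cases vs completed data."""

    delta_mean: dict[str, float]
    delta_variance: dict[str, float]
    max_abs_delta_r: float
    imputed_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {"delta_mean": self.delta_mean, "delta_variance": self.delta_variance,
                "max_abs_delta_r": self.max_abs_delta_r,
                "imputed_counts": self.imputed_counts}


def _normalized_features(df: pd.DataFrame, scaling: dict[str, tuple[float, float]],
                         exclude: str) -> np.ndarray:
    """Feature matrix for distance computation: scaled numerics, raw category
    codes (compared by simple matching), NaN where missing; `exclude` and the
    target are dropped."""
    cols = [c for c in PREDICTORS if c != exclude]
    out = np.empty((len(df), len(cols)))
    for j, c in enumerate(cols):
        v = df[c].to_numpy(dtype=float)
        if c in NUMERIC:
            lo, hi = scaling[c]
            out[:, j] = (v - lo) / (hi - lo) if hi > lo else np.where(np.isnan(v), np.nan, 0.0)
        else:
            out[:, j] = v
    return out


def _distances(query: np.ndarray, donors: np.ndarray, numeric_mask: np.ndarray) -> np.ndarray:
    """Normalized Euclidean distance over co-observed features.

    Numeric features contribute squared scaled differences; categorical and
    binary features contribute 0/1 mismatch.  The sum is divided by the
    number of co-observed features, so the distance is scale-free in the
    feature count.
    """
    diff = donors - query[None, :]
    sq = np.where(numeric_mask[None, :], diff ** 2, (diff != 0).astype(float))
    observed = ~np.isnan(donors) & ~np.isnan(query)[None, :]
    sq = np.where(observed, sq, 0.0)
    counts = observed.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.where(counts > 0, sq.sum(axis=1) / np.maximum(counts, 1), np.inf))
    return d


def membership_weights(distances: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian membership kernel exp(-d^2 / (2 sigma^2)), normalized to sum 1."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ImputationError("empty donor pool")
    w = np.exp(-(distances ** 2) / (2.0 * bandwidth ** 2))
    total = w.sum()
    if total == 0 or not np.isfinite(total):
        # all donors infinitely far (no co-observed features): fall back to uniform
        w = np.ones_like(w)
        total = w.sum()
    return w / total


class FuzzyImputer:
    """Fit on a (training) cohort; impute that cohort or any other."""

    def __init__(self, config: ImputationConfig | None = None,
                 collect_diagnostics: bool = False):
        self.config = config or ImputationConfig()
        self.collect_diagnostics = collect_diagnostics
        #: per imputed cell: row, field, donor-pool size, distance and
        #: membership summaries, imputed value (filled when enabled)
        self.diagnostics_: list[dict] = []
        self._donors: pd.DataFrame | None = None
        self.scaling_: dict[str, tuple[float, float]] = {}
        self.fitted_on_n_: int | None = None
        self.fit_fingerprint_: int | None = None

    def fit(self, cohort: Cohort) -> "FuzzyImputer":
        if cohort.n == 0:
            raise ImputationError("cannot fit an imputer on an empty cohort")
        self._donors = cohort.df.copy()
        self.scaling_ = {}
        for c in NUMERIC:
            v = self._donors[c].dropna()
            self.scaling_[c] = (float(v.min()), float(v.max())) if len(v) else (0.0, 0.0)
        self.fitted_on_n_ = cohort.n
        self.fit_fingerprint_ = zlib.crc32(self._donors.to_numpy().tobytes())
        return self

    def transform(self, cohort: Cohort) -> Cohort:
        if self._donors is None:
            raise RuntimeError("FuzzyImputer.transform called before fit")
        cfg = self.config
        df = cohort.df.copy()
        missing_fields = [c for c in PREDICTORS if df[c].isna().any()]
        if not missing_fields:
            return Cohort(df)
        # identity-transform guard: when imputing the fitted cohort itself, a
        # record must not donate to its own missing cell (it cannot anyway —
        # it lacks the field — but shared rows are fine).
        for fieldname in missing_fields:
            donors_df = self._donors[self._donors[fieldname].notna()]
            rows = np.flatnonzero(df[fieldname].isna().to_numpy())
            if len(donors_df) == 0:
                raise ImputationError(
                    f"field {fieldname!r} has no complete donor records; "
                    f"unimputable rows: {rows.tolist()}")
            donor_feats = _normalized_features(donors_df, self.scaling_, fieldname)
            query_feats = _normalized_features(df.iloc[rows], self.scaling_, fieldname)
            numeric_mask = np.array([c in NUMERIC for c in PREDICTORS if c != fieldname])
            donor_values = donors_df[fieldname].to_numpy(dtype=float)
            field_id = COLUMNS.index(fieldname)
            for q, i in enumerate(rows):
                d = _distances(query_feats[q], donor_feats, numeric_mask)
                rng = np.random.default_rng([cfg.seed, int(i), field_id])
                size = min(cfg.k_donors, len(d))
                numeric_draws = []
                membership_totals: dict[float, float] = {}
                for _ in range(cfg.m):
                    subset = (np.arange(len(d)) if size == len(d)
                              else rng.choice(len(d), size=size, replace=False))
                    w = membership_weights(d[subset], cfg.kernel_bandwidth)
                    vals = donor_values[subset]
                    if fieldname in NUMERIC:
                        numeric_draws.append(float(w @ vals))
                    else:
                        for v, wv in zip(vals, w):
                            membership_totals[v] = membership_totals.get(v, 0.0) + wv
                if fieldname in NUMERIC:
                    value = float(np.mean(numeric_draws))
                else:
                    value = max(sorted(membership_totals),
                                key=lambda v: membership_totals[v])
                df.iloc[i, df.columns.get_loc(fieldname)] = value
                if self.collect_diagnostics:
                    finite = d[np.isfinite(d)]
                    self.diagnostics_.append({
                        "row": int(i), "field": fieldname,
                        "n_donors": int(len(d)), "draws": cfg.m,
                        "subset_size": int(size),
                        "min_distance": float(finite.min()) if len(finite) else None,
                        "mean_distance": float(finite.mean()) if len(finite) else None,
                        "imputed_value": float(value),
                    })
        return Cohort(df)

    def fit_transform(self, cohort: Cohort) -> Cohort:
        return self.fit(cohort).transform(cohort)


def fuzzy_impute(cohort: Cohort, config: ImputationConfig | None = None) -> Cohort:
    """Complete `cohort` using its own records as donors."""
    return FuzzyImputer(config).fit_transform(cohort)


def imputation_report(before: Cohort, after: Cohort) -> ImputationReport:
    """Compare observed-cases statistics against the completed data.

    Per numeric feature: change in mean and variance.  ``max_abs_delta_r`` is
    the largest absolute change over pairwise numeric correlations
    (pairwise-complete before, complete after).
    """
    if before.n != after.n:
        raise SchemaError(f"record counts differ: {before.n} vs {after.n}")
    if list(before.df.columns) != list(after.df.columns):
        raise SchemaError("schema mismatch between cohorts")
    delta_mean, delta_var = {}, {}
    for c in NUMERIC:
        b, a = before.df[c].dropna(), after.df[c]
        delta_mean[c] = float(a.mean() - b.mean())
        delta_var[c] = float(a.var(ddof=1) - b.var(ddof=1))
    num = list(NUMERIC)
    r_before = before.df[num].corr()
    r_after = after.df[num].corr()
    dr = (r_after - r_before).abs().to_numpy()
    iu = np.triu_indices(len(num), k=1)
    max_dr = float(np.nanmax(dr[iu])) if len(num) > 1 else 0.0
    counts = {c: int(before.df[c].isna().sum() - after.df[c].isna().sum())
              for c in PREDICTORS
              if before.df[c].isna().sum() != after.df[c].isna().sum()}
    return ImputationReport(delta_mean=delta_mean, delta_variance=delta_var,
                            max_abs_delta_r=max_dr, imputed_counts=counts)
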