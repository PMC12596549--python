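"""Synthetic cohort generation with known risk structure and injectable bias.

Records follow the 14-field heart-disease schema.  The outcome is drawn from a
logistic model on severity-scored predictors, with the intercept calibrated
per demographic group (sex crossed with the age-50 split) so that every group
hits the requested base prevalence; a per-group ``bias_shift`` in log-odds is
then added on top to inject controlled unfairness.  Calibrating per group
keeps subgroup prevalences equal at ``bias_shift = 0`` even though age itself
carries risk within each group.

A larger "source-domain" corpus for transfer-learning pretraining is produced
by the same machinery with optionally shifted feature means and rescaled risk
coefficients (a related but non-identical domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .schema import (COLUMNS, NUMERIC, NUMERIC_RANGES, CATEGORICAL_DOMAINS,
                     Cohort, AGE_SPLIT)

GROUPS = ("male:lt50", "male:ge50", "female:lt50", "female:ge50")

#: Demographic mix loosely matching the Cleveland cohort (two-thirds male,
#: most patients over 50).
DEFAULT_GROUP_MIX = {
    "male:lt50": 0.20, "male:ge50": 0.48, "female:lt50": 0.09, "female:ge50": 0.23,
}

#: Per-feature log-odds effects on severity scores in [0, 1].  Chest-pain
#: type, ST depression, thalassemia, max heart rate and age dominate by
#: construction, so attribution methods have a known ranking to recover.
#: thalach is protective (higher max heart rate, lower risk).
DEFAULT_RISK_COEFFICIENTS = {
    "cp": 2.6, "oldpeak": 2.2, "thal": 2.0, "thalach": -1.8, "age": 1.2,
    "ca": 1.4, "exang": 0.8, "slope": 0.6, "trestbps": 0.5, "chol": 0.4,
    "restecg": 0.3, "fbs": 0.1, "sex": 0.0,
}

#: Missingness confined to thal/ca by default, at roughly the rates seen in
#: the Cleveland subset (2/303 and 4/303).
DEFAULT_MISSING_RATES = {"thal": 2 / 303, "ca": 4 / 303}

_THAL_SCORE = {3: 0.0, 6: 0.5, 7: 1.0}


class SpecError(ValueError):
    """A cohort specification violates its invariants."""


@dataclass(frozen=True)
class CohortSpec:
    """Everything that determines a synthetic cohort, including the seed.

    Identical specs (including ``seed``) produce byte-identical cohorts.
    """

    n: int
    seed: int
    prevalence: float = 0.46
    group_mix: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_MIX))
    risk_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_RISK_COEFFICIENTS))
    bias_shift: dict = field(default_factory=dict)
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    #: draw y deterministically as 1{p > 0.5} instead of Bernoulli(p); makes
    #: the cohort exactly linearly separable in the severity scores
    deterministic_labels: bool = False

    def __post_init__(self):
        if self.n < 0:
            raise SpecError(f"n must be >= 0, got {self.n}")
        if not (0.0 < self.prevalence < 1.0):
            raise SpecError(f"prevalence must lie in (0,1), got {self.prevalence}")
        if set(self.group_mix) != set(GROUPS):
            raise SpecError(f"group_mix must cover exactly {GROUPS}")
        total = sum(self.group_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"group_mix must sum to 1, got {total}")
        if any(p < 0 for p in self.group_mix.values()):
            raise SpecError("group_mix proportions must be nonnegative")
        for f_, r in self.missing_rates.items():
            if not (0.0 <= r <= 1.0):
                raise SpecError(f"missing rate for {f_!r} must lie in [0,1], got {r}")
        for g in self.bias_shift:
            if g not in GROUPS:
                raise SpecError(f"bias_shift key {g!r} is not a demographic group")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class DomainShift:
    """Distribution-shift knobs for the pretraining source domain.

    ``mean_shifts`` adds a constant to the named continuous features (their
    clipping windows move with them); ``coefficient_scale`` rescales every
    risk coefficient.  The zero shift reproduces the target-domain generator
    exactly at the same spec and seed.
    """

    mean_shifts: dict = field(default_factory=dict)
    coefficient_scale: float = 1.0

    def is_null(self) -> bool:
        return self.coefficient_scale == 1.0 and not any(self.mean_shifts.values())


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def severity_scores(df: pd.DataFrame) -> pd.DataFrame:
    """Map raw predictor values to severity scores in [0, 1].

    Numerics are scaled by their nominal ranges; ordinal categoricals are
    spread evenly over [0, 1]; thalassemia uses its conventional ordering
    normal < fixed defect < reversible defect.
    """
    out = pd.DataFrame(index=df.index)
    for name in NUMERIC:
        lo, hi = NUMERIC_RANGES[name]
        out[name] = np.clip((df[name] - lo) / (hi - lo), 0.0, 1.0)
    for name in ("sex", "fbs", "exang"):
        out[name] = df[name]
    out["cp"] = (df["cp"] - 1) / 3.0
    out["restecg"] = df["restecg"] / 2.0
    out["slope"] = (df["slope"] - 1) / 2.0
    out["ca"] = df["ca"] / 3.0
    out["thal"] = df["thal"].map(_THAL_SCORE)
    return out


def _linear_risk(df: pd.DataFrame, coefficients: dict) -> np.ndarray:
    scores = severity_scores(df)
    z = np.zeros(len(df))
    for name, beta in coefficients.items():
        z += beta * scores[name].to_numpy()
    return z


def _calibrate_intercept(s: np.ndarray, prevalence: float) -> float:
    """Solve mean(sigmoid(s + c)) = prevalence for c by bisection."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(s + mid).mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_predictors(spec: CohortSpec, rng: np.random.Generator,
                       shift: DomainShift) -> tuple[pd.DataFrame, np.ndarray]:
    n = spec.n
    groups = rng.choice(len(GROUPS), size=n, p=[spec.group_mix[g] for g in GROUPS])
    group_names = np.array(GROUPS)[groups]
    sex = np.array([1.0 if g.startswith("male") else 0.0 for g in group_names])
    young = np.array([g.endswith("lt50") for g in group_names])

    age = np.where(young,
                   np.clip(rng.normal(44.0, 4.0, n), 29, AGE_SPLIT - 1),
                   np.clip(rng.normal(58.0, 6.0, n), AGE_SPLIT, 77))

    def numeric(name, mu, sd):
        lo, hi = NUMERIC_RANGES[name]
        delta = shift.mean_shifts.get(name, 0.0)
        return np.clip(rng.normal(mu + delta, sd, n), lo + delta, hi + delta)

    trestbps = numeric("trestbps", 131.0, 17.0)
    chol = numeric("chol", 246.0, 51.0)
    thalach = numeric("thalach", 150.0, 22.0)
    oldpeak = np.clip(rng.gamma(shape=1.2, scale=0.9, size=n), *NUMERIC_RANGES["oldpeak"])

    def categorical(domain, probs):
        return rng.choice(list(map(float, domain)), size=n, p=probs)

    df = pd.DataFrame({
        "age": np.round(age),
        "sex": sex,
        "cp": categorical(CATEGORICAL_DOMAINS["cp"], [0.08, 0.17, 0.28, 0.47]),
        "trestbps": np.round(trestbps),
        "chol": np.round(chol),
        "fbs": (rng.random(n) < 0.15).astype(float),
        "restecg": categorical(CATEGORICAL_DOMAINS["restecg"], [0.50, 0.02, 0.48]),
        "thalach": np.round(thalach),
        "exang": (rng.random(n) < 0.33).astype(float),
        "oldpeak": np.round(oldpeak, 1),
        "slope": categorical(CATEGORICAL_DOMAINS["slope"], [0.47, 0.46, 0.07]),
        "ca": categorical(CATEGORICAL_DOMAINS["ca"], [0.58, 0.21, 0.13, 0.08]),
        "thal": categorical(CATEGORICAL_DOMAINS["thal"], [0.55, 0.06, 0.39]),
    })
    return df, group_names


def _generate(spec: CohortSpec, shift: DomainShift) -> Cohort:
    rng = np.random.default_rng(spec.seed)
    if spec.n == 0:
        return Cohort(pd.DataFrame(columns=list(COLUMNS)))
    df, group_names = _sample_predictors(spec, rng, shift)

    coefficients = {k: v * shift.coefficient_scale
                    for k, v in spec.risk_coefficients.items()}
    s = _linear_risk(df, coefficients)
    z = np.empty(spec.n)
    for g in GROUPS:
        mask = group_names == g
        if not mask.any():
            continue
        c = _calibrate_intercept(s[mask], spec.prevalence)
        z[mask] = s[mask] + c + spec.bias_shift.get(g, 0.0)
    p = _sigmoid(z)
    if spec.deterministic_labels:
        df["target"] = (p > 0.5).astype(float)
    else:
        df["target"] = (rng.random(spec.n) < p).astype(float)

    for name, rate in spec.missing_rates.items():
        if rate > 0:
            df.loc[rng.random(spec.n) < rate, name] = np.nan
    return Cohort(df)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a target-domain cohort from `spec` (deterministic in the seed)."""
    return _generate(spec, DomainShift())


def generate_pretrain_corpus(spec: CohortSpec, shift: DomainShift | None = None) -> Cohort:
    """Draw the larger source-domain corpus used to pretrain the encoder.

    With a null `shift` this is exactly :func:`generate_cohort`; nonzero
    shifts move continuous-feature means and rescale risk coefficients to
    emulate a related cardiovascular population.
    """
    return _generate(spec, shift or DomainShift())


def pretrain_spec(seed: int, n: int = 3030) -> CohortSpec:
    """Default source-domain spec: ten times a typical target cohort."""
    return CohortSpec(n=n, seed=seed, prevalence=0.5)


DEFAULT_DOMAIN_SHIFT = DomainShift(
    mean_shifts={"chol": 15.0, "trestbps": 6.0, "thalach": -8.0},
    coefficient_scale=1.15,
)


def strongly_separable_spec(n: int = 400, seed: int = 0) -> CohortSpec:
    """An exactly linearly separable cohort: default coefficients scaled
    fourfold, noise-free labels, balanced classes, no missingness."""
    coeffs = {k: 4.0 * v for k, v in DEFAULT_RISK_COEFFICIENTS.items()}
    return CohortSpec(n=n, seed=seed, prevalence=0.5,
                      risk_coefficients=coeffs, missing_rates={},
                      deterministic_labels=True)


def cleveland_standin(seed: int = 2026) -> Cohort:
    """A synthetic stand-in with the shape of the Cleveland subset.

    303 records, with exactly 2 `thal` and 4 `ca` cells masked (the real
    subset's missingness pattern).  This is generated data — it emulates the
    schema and missingness shape only, not the real joint distribution.
    """
    spec = CohortSpec(n=303, seed=seed, prevalence=0.46, missing_rates={})
    cohort = generate_cohort(spec)
    rng = np.random.default_rng(seed + 1)
    df = cohort.df
    df.loc[rng.choice(303, size=2, replace=False), "thal"] = np.nan
    df.loc[rng.choice(303, size=4, replace=False), "ca"] = np.nan
    return Cohort(df)
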