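"""Model / Results objects tying the pipeline together.

`IHDClassifier` is constructed from a cohort (records in the 14-field
heart-disease schema); `fit()` imputes, encodes, reweights and trains,
returning an `IHDResults` that carries the trained state, diagnostics and a
`summary()` table, and exposes prediction, evaluation and Shapley
attribution.  Cross-validation and the component-ablation grid hang off the
model object.

Example
-------
>>> from cardiofair import IHDClassifier, simulate
>>> cohort = simulate.generate_cohort(simulate.CohortSpec(n=300, seed=7))
>>> res = IHDClassifier(cohort).fit()          # doctest: +SKIP
>>> print(res.summary())                        # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .explain import Attribution, global_importance, shap_attribute
from .fairness import (GroupWeightTable, group_proportions,
                       inverse_frequency_weights, sample_weights)
from .impute import FuzzyImputer
from .metrics import MetricsReport, evaluate_predictions
from .network import ModelState, predict_proba, save_checkpoint, transfer_init, init_state
from .pipeline import (AblationResult, CVResult, RunConfig, ablate,
                       cross_validate, pretrain, train)
from .preprocess import EncodedMatrix, Encoder
from .schema import Cohort
from . import io as _io
from .network import Checkpoint, load_checkpoint


class IHDClassifier:
    """Ischemic-heart-disease risk classifier on tabular clinical records."""

    def __init__(self, cohort: Cohort, config: RunConfig | None = None,
                 checkpoint: Checkpoint | str | Path | None = None):
        self.cohort = cohort
        self.config = config or RunConfig()
        if isinstance(checkpoint, (str, Path)):
            checkpoint = load_checkpoint(checkpoint)
        elif checkpoint is None and self.config.transfer_checkpoint:
            checkpoint = load_checkpoint(self.config.transfer_checkpoint)
        self.checkpoint = checkpoint

    # ------------------------------------------------------------- builders
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "IHDClassifier":
        return cls(Cohort(df), **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, dialect: str = "headerless-processed",
                 **kwargs) -> "IHDClassifier":
        return cls(_io.read_uci_csv(path, dialect), **kwargs)

    # ------------------------------------------------------------------ fit
    def fit(self) -> "IHDResults":
        cfg = self.config
        imputer = FuzzyImputer(cfg.imputation).fit(self.cohort)
        completed = imputer.transform(self.cohort)
        encoder = Encoder().fit(completed)
        matrix = encoder.transform(completed)
        weight_table = None
        weights = None
        if cfg.fairness_reweighting:
            keys = completed.group_keys()
            weight_table = inverse_frequency_weights(group_proportions(keys))
            weights = sample_weights(keys, weight_table)
        state0 = init_state(matrix.feature_names, hidden_size=cfg.lstm_units,
                            lam=cfg.lam, seed=cfg.seed, pool=cfg.pool,
                            use_residual_attention=cfg.residual_attention)
        if self.checkpoint is not None:
            state0 = transfer_init(state0, self.checkpoint, strict=True,
                                   head_seed=[cfg.seed, 1])
        state, trace = train(matrix.values, matrix.y, cfg, weights=weights,
                             initial_state=state0, seed=[cfg.seed, 2])
        return IHDResults(model=self, state=state, loss_trace=trace,
                          imputer=imputer, encoder=encoder, matrix=matrix,
                          weight_table=weight_table)

    # --------------------------------------------------------- evaluation
    def cross_validate(self) -> CVResult:
        return cross_validate(self.cohort, self.config, checkpoint=self.checkpoint)

    def ablate(self, checkpoint: Checkpoint | None = None) -> AblationResult:
        ck = checkpoint or self.checkpoint
        if ck is None:
            ck = pretrain(self.config)
        return ablate(self.cohort, self.config, ck)


@dataclass
class IHDResults:
    """A fitted classifier: trained parameters, preprocessing state and
    diagnostics."""

    model: IHDClassifier
    state: ModelState
    loss_trace: list[float]
    imputer: FuzzyImputer
    encoder: Encoder
    matrix: EncodedMatrix
    weight_table: GroupWeightTable | None = None
    _train_metrics: MetricsReport | None = field(default=None, repr=False)

    # ----------------------------------------------------------- prediction
    def _encode(self, cohort: Cohort | None) -> EncodedMatrix:
        if cohort is None:
            return self.matrix
        completed = self.imputer.transform(cohort)
        return self.encoder.transform(completed)

    def predict_proba(self, cohort: Cohort | None = None) -> np.ndarray:
        return predict_proba(self.state, self._encode(cohort).values)

    def predict(self, cohort: Cohort | None = None, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(cohort) >= threshold).astype(int)

    def evaluate(self, cohort: Cohort | None = None) -> MetricsReport:
        m = self._encode(cohort)
        return evaluate_predictions(m.y, predict_proba(self.state, m.values))

    # -------------------------------------------------------- explanation
    def model_fn(self):
        state = self.state
        return lambda X: predict_proba(state, X)

    def explain(self, cohort: Cohort | None = None, indices=None,
                mode: str = "sampled", n_permutations: int = 32,
                background_size: int = 100, seed: int = 0) -> list[Attribution]:
        """Per-record Shapley attributions against a seeded training-set
        background (capped at `background_size` rows)."""
        m = self._encode(cohort)
        rng = np.random.default_rng(seed)
        bg = self.matrix.values
        if len(bg) > background_size:
            bg = bg[rng.choice(len(bg), size=background_size, replace=False)]
        rows = range(m.n) if indices is None else indices
        return [shap_attribute(self.model_fn(), bg, m.values[i],
                               m.feature_names, mode=mode,
                               n_permutations=n_permutations, seed=seed + i)
                for i in rows]

    def global_importance(self, **kwargs) -> list[tuple[str, float]]:
        return global_importance(self.explain(**kwargs))

    # -------------------------------------------------------------- export
    def save(self, path: str | Path) -> None:
        save_checkpoint(self.state, path,
                        provenance=f"fitted on n={self.matrix.n} "
                                   f"config={self.model.config.config_hash()}")

    def summary(self) -> str:
        cfg = self.model.config
        m = self.evaluate()
        lines = [
            "Residual-attention BiLSTM classifier (fitted)",
            "=" * 46,
            f"records: {self.matrix.n}   encoded columns: {self.matrix.d}",
            f"hidden units: {cfg.lstm_units}   lambda: {cfg.lam}   "
            f"optimizer: {cfg.optimizer} (lr={cfg.learning_rate})",
            f"epochs: {cfg.epochs}   batch: {cfg.batch_size}   seed: {cfg.seed}",
            f"residual attention: {'on' if cfg.residual_attention else 'off'}   "
            f"transfer init: {'yes' if self.model.checkpoint is not None else 'no'}   "
            f"fairness reweighting: {'on' if cfg.fairness_reweighting else 'off'}",
            f"final epoch loss: {self.loss_trace[-1]:.4f}" if self.loss_trace
            else "final epoch loss: n/a (0 epochs)",
            "-" * 46,
            "training-set performance (threshold 0.5):",
            f"  accuracy {m.accuracy:.3f}  precision {m.precision:.3f}  "
            f"recall {m.recall:.3f}",
            f"  specificity {m.specificity:.3f}  F1 {m.f1:.3f}  AUC {m.auc:.3f}",
            f"  confusion TP={m.tp} FP={m.fp} TN={m.tn} FN={m.fn}",
        ]
        if self.weight_table is not None:
            ws = ", ".join(f"{g}: {w:.2f}" for g, w in
                           sorted(self.weight_table.weights.items()))
            lines.append(f"group weights (mean 1): {ws}")
        return "\n".join(lines)
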