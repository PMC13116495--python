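"""Hybrid encoder + random-forest risk classifier.

The full model chains: schema validation -> bin refresh & index coding ->
train-split z-scoring -> SHAP-importance input weighting -> MLP encoder ->
latent representations -> random-forest head (200 trees, max_depth 10,
balanced class weights) -> probability -> calibrated decision threshold.

The threshold is chosen on validation data as the candidate maximizing the
positive-class F1 (an F-beta alternative is configurable), with candidates
taken as midpoints between consecutive sorted unique validation
probabilities plus 0.5, and ties broken toward the larger threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .encoder import (
    EncoderConfig,
    TabularEncoder,
    TrainingConfig,
    WeightedInput,
    extract_latents,
    train_encoder,
)
from .cohort import split_cohort
from .preprocess import NormalizationStats, encode_cohort, fit_normalization
from .schema import LABEL_COLUMN, Schema, SchemaError, default_schema, validate_schema
from .weighting import (
    DEFAULT_GAMMA,
    DEFAULT_LAMBDA,
    ImportanceWeights,
    apply_weights,
    estimate_importance_weights,
)

__all__ = [
    "RFHeadConfig",
    "PipelineConfig",
    "HybridModel",
    "fit_rf_head",
    "optimize_threshold",
    "classify",
    "train_hybrid",
]

DEFAULT_THRESHOLD = 0.517  # tuned operating point of the reference configuration


@dataclass(frozen=True)
class RFHeadConfig:
    n_trees: int = 200
    max_depth: int = 10
    balanced: bool = True
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end training configuration of the hybrid classifier."""

    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    rf_head: RFHeadConfig = field(default_factory=RFHeadConfig)
    lambda_: float = DEFAULT_LAMBDA
    gamma_: float = DEFAULT_GAMMA
    use_shap_weighting: bool = True
    optimize_decision_threshold: bool = True
    threshold_beta: float = 1.0
    val_fraction: float = 0.2
    prelim_rf_trees: int = 100
    prelim_rf_depth: int = 6
    seed: int = 0

    def without_shap(self) -> "PipelineConfig":
        """Ablation arm: importance weighting disabled (weights all 1)."""
        from dataclasses import replace

        return replace(self, use_shap_weighting=False, lambda_=0.0)

    def without_imbalance(self) -> "PipelineConfig":
        """Ablation arm: plain loss/sampler, unbalanced forest, threshold 0.5."""
        from dataclasses import replace

        return replace(
            self,
            training=replace(
                self.training, pos_weight=1.0, sampler="plain", loss_kind="weighted_bce"
            ),
            rf_head=replace(self.rf_head, balanced=False),
            optimize_decision_threshold=False,
        )

    def baseline(self) -> "PipelineConfig":
        return self.without_shap().without_imbalance()


def fit_rf_head(
    latents: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 200,
    max_depth: int = 10,
    balanced: bool = True,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the forest head on latent representations."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present to fit the forest head")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        class_weight="balanced" if balanced else None,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(np.asarray(latents, dtype=float), y)
    return rf


def _fbeta(tp: int, fp: int, fn: int, beta: float) -> float:
    b2 = beta * beta
    denom = (1 + b2) * tp + fp + b2 * fn
    return (1 + b2) * tp / denom if denom > 0 else 0.0


def optimize_threshold(
    probs: np.ndarray, labels: np.ndarray, beta: float = 1.0
) -> float:
    """Decision threshold maximizing positive-class F-beta on validation data.

    Candidates are the midpoints between consecutive sorted unique
    probabilities plus 0.5 (exhaustive over achievable confusion matrices);
    ties break toward the larger threshold, favoring specificity.  A
    degenerate probability vector (all values equal) returns 0.5 with a
    warning.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in the validation labels")
    uniq = np.unique(probs)
    if uniq.size < 2:
        warnings.warn("degenerate probability vector; returning threshold 0.5")
        return 0.5
    candidates = np.concatenate([(uniq[:-1] + uniq[1:]) / 2.0, [0.5]])
    best_t, best_f = 0.5, -1.0
    for t in np.sort(candidates):
        pred = probs > t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        f = _fbeta(tp, fp, fn, beta)
        if f >= best_f:  # >= breaks ties toward the larger threshold
            best_f, best_t = f, float(t)
    return best_t


def classify(probs: np.ndarray, threshold: float) -> np.ndarray:
    """Positive iff probability strictly exceeds the threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly in (0, 1)")
    return (np.asarray(probs, dtype=float) > threshold).astype(np.int64)


@dataclass
class HybridModel:
    """Trained end-to-end risk model with its preprocessing state."""

    schema: Schema
    norm_stats: NormalizationStats
    weights: ImportanceWeights
    encoder: TabularEncoder
    rf_head: RandomForestClassifier
    threshold: float
    config: PipelineConfig
    history: pd.DataFrame | None = None

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("decision threshold must lie strictly in (0, 1)")

    def _prepare(self, table: pd.DataFrame) -> WeightedInput:
        report = validate_schema(table, self.schema, check_label=False)
        if not report.ok:
            raise SchemaError(
                f"table fails schema validation ({len(report)} issues; first: "
                f"{report.issues[0]})"
            )
        encoded = encode_cohort(table, self.schema, self.norm_stats)
        return apply_weights(encoded, self.weights)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """End-to-end PPC probability per patient, in table row order."""
        inputs = self._prepare(table)
        latents = extract_latents(self.encoder, inputs)
        return self.rf_head.predict_proba(latents)[:, 1]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return classify(self.predict_proba(table), self.threshold)

    def risk_labels(self, table: pd.DataFrame) -> np.ndarray:
        """'high'/'low' per patient, by the calibrated threshold."""
        return np.where(self.predict(table) == 1, "high", "low")


def train_hybrid(
    train_table: pd.DataFrame,
    config: PipelineConfig | None = None,
    schema: Schema | None = None,
    val_table: pd.DataFrame | None = None,
) -> HybridModel:
    """Train the full hybrid pipeline on a labelled cohort.

    When no validation table is given, a stratified ``val_fraction`` split of
    the training cohort is held out for encoder early stopping and threshold
    calibration.  Normalization statistics, importance weights and all model
    parameters are fit on the training portion only.
    """
    config = config or PipelineConfig()
    schema = schema or default_schema()
    if val_table is None:
        train_table, val_table = split_cohort(
            train_table, config.val_fraction, stratified=True, seed=config.seed
        )

    stats = fit_normalization(train_table, schema)
    enc_train = encode_cohort(train_table, schema, stats)
    enc_val = encode_cohort(val_table, schema, stats)

    if config.use_shap_weighting and config.lambda_ > 0:
        weights = estimate_importance_weights(
            enc_train,
            lambda_=config.lambda_,
            gamma_=config.gamma_,
            n_trees=config.prelim_rf_trees,
            max_depth=config.prelim_rf_depth,
            seed=config.seed,
        )
    else:
        weights = ImportanceWeights.uniform(enc_train.feature_order)

    in_train = apply_weights(enc_train, weights)
    in_val = apply_weights(enc_val, weights)

    encoder, history = train_encoder(in_train, in_val, config.encoder, config.training)

    lat_train = extract_latents(encoder, in_train)
    rf = fit_rf_head(
        lat_train,
        in_train.labels,
        n_trees=config.rf_head.n_trees,
        max_depth=config.rf_head.max_depth,
        balanced=config.rf_head.balanced,
        seed=config.rf_head.seed,
    )

    if config.optimize_decision_threshold:
        val_probs = rf.predict_proba(extract_latents(encoder, in_val))[:, 1]
        threshold = optimize_threshold(val_probs, in_val.labels, config.threshold_beta)
    else:
        threshold = 0.5

    return HybridModel(
        schema=schema,
        norm_stats=stats,
        weights=weights,
        encoder=encoder,
        rf_head=rf,
        threshold=threshold,
        config=config,
        history=history,
    )
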