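"""SHAP-importance-based input reweighting.

A preliminary random forest is fit on the (index-coded) training table and
its mean absolute SHAP values give a per-feature global importance.  After
max-normalization (imp in [0, 1]) the encoder-input weight of feature i is

    w_i = 1 + lambda * imp_i ** gamma

so the most important feature is scaled by 1 + lambda, an uninformative
feature by 1, and no feature is ever dropped.  Tuned defaults:
lambda = 0.27, gamma = 0.82.  Importance is estimated on training data only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .encoder import WeightedInput
from .preprocess import EncodedCohort
from .treeshap import TreeEnsembleExplainer

__all__ = [
    "ImportanceWeights",
    "fit_preliminary_rf",
    "compute_mean_abs_shap",
    "normalize_importance",
    "compute_feature_weights",
    "apply_weights",
    "plot_importance",
    "estimate_importance_weights",
]

DEFAULT_LAMBDA = 0.27
DEFAULT_GAMMA = 0.82


@dataclass(frozen=True)
class ImportanceWeights:
    """Per-feature importance and the derived encoder-input weights."""

    feature_names: tuple[str, ...]
    raw_importance: np.ndarray
    imp: np.ndarray
    lambda_: float
    gamma_: float
    w: np.ndarray

    def __post_init__(self):
        if np.any(self.imp < 0) or np.any(self.imp > 1):
            raise ValueError("normalized importance must lie in [0, 1]")

    def weight_of(self, name: str) -> float:
        return float(self.w[self.feature_names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.feature_names),
                "raw_importance": self.raw_importance,
                "imp": self.imp,
                "w": self.w,
            }
        )

    @classmethod
    def uniform(cls, feature_names) -> "ImportanceWeights":
        """Unit weights for every feature (the lambda = 0 limit)."""
        d = len(feature_names)
        return cls(
            tuple(feature_names),
            np.zeros(d),
            np.zeros(d),
            0.0,
            DEFAULT_GAMMA,
            np.ones(d),
        )


def fit_preliminary_rf(
    X: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 100,
    max_depth: int = 6,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the simplified forest used only for importance estimation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("cannot fit a preliminary forest on an empty table")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def compute_mean_abs_shap(model, X: np.ndarray) -> np.ndarray:
    """Mean absolute SHAP value per feature over the given patients."""
    X = np.asarray(X, dtype=float)
    if hasattr(model, "n_features_in_") and X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature count mismatch: model expects {model.n_features_in_}, got {X.shape[1]}"
        )
    explainer = TreeEnsembleExplainer(model, class_index=1)
    phi = explainer.shap_values(X)
    return np.abs(phi).mean(axis=0)


def mean_abs_shap_over_folds(models, fold_tables) -> np.ndarray:
    """Average per-feature mean-|SHAP| across cross-validation folds
    (each fold weighted equally)."""
    per_fold = [compute_mean_abs_shap(m, X) for m, X in zip(models, fold_tables)]
    return np.mean(per_fold, axis=0)


def normalize_importance(raw: np.ndarray) -> np.ndarray:
    """Max-normalize a nonnegative importance vector into [0, 1].

    An all-zero vector maps to all zeros (with a warning) so that the weight
    formula degenerates to w = 1 everywhere.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw importance must be nonnegative")
    top = raw.max() if raw.size else 0.0
    if top == 0.0:
        warnings.warn("all-zero importance vector; weights degenerate to 1")
        return np.zeros_like(raw)
    return raw / top


def compute_feature_weights(
    imp: np.ndarray,
    feature_names,
    lambda_: float = DEFAULT_LAMBDA,
    gamma_: float = DEFAULT_GAMMA,
    raw_importance: np.ndarray | None = None,
) -> ImportanceWeights:
    """Evaluate w_i = 1 + lambda * imp_i ** gamma exactly."""
    imp = np.asarray(imp, dtype=float)
    if np.any(imp < 0) or np.any(imp > 1):
        raise ValueError("imp must lie in [0, 1]")
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    if gamma_ <= 0:
        raise ValueError("gamma_ must be > 0")
    w = 1.0 + lambda_ * imp**gamma_
    raw = imp.copy() if raw_importance is None else np.asarray(raw_importance, float)
    return ImportanceWeights(tuple(feature_names), raw, imp, lambda_, gamma_, w)


def apply_weights(encoded: EncodedCohort, weights: ImportanceWeights) -> WeightedInput:
    """Scale encoder inputs by their importance weights.

    Numeric columns are multiplied elementwise by w_i; each categorical or
    boolean feature's embedding vector is scaled by its w_i at lookup time.
    With lambda = 0 the result reproduces the unweighted input exactly.
    """
    if tuple(weights.feature_names) != tuple(encoded.feature_order):
        raise ValueError("weights do not cover the encoded feature order")
    d_num = len(encoded.numeric_names)
    w_num = weights.w[:d_num]
    w_code = weights.w[d_num:]
    return WeightedInput(
        numeric=encoded.numeric * w_num,
        codes=encoded.codes,
        code_weights=np.asarray(w_code, dtype=float),
        cardinalities=encoded.cardinalities,
        numeric_names=encoded.numeric_names,
        code_names=encoded.code_names,
        labels=encoded.labels,
    )


def plot_importance(weights: ImportanceWeights, path=None, top: int = 15):
    """Horizontal bar plot of the top mean-|SHAP| importances.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = (
        weights.to_frame().sort_values("raw_importance", ascending=True).tail(top)
    )
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(frame) + 1))
    ax.barh(frame["feature"], frame["raw_importance"], color="#4C72B0")
    ax.set_xlabel("mean |SHAP value|")
    ax.set_title("Global feature importance")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def estimate_importance_weights(
    encoded: EncodedCohort,
    lambda_: float = DEFAULT_LAMBDA,
    gamma_: float = DEFAULT_GAMMA,
    n_trees: int = 100,
    max_depth: int = 6,
    seed: int = 0,
) -> ImportanceWeights:
    """Full importance pipeline on a training cohort.

    Fits the preliminary forest, computes mean-|SHAP| importance on the same
    training rows, max-normalizes, and evaluates the weight formula.
    """
    X = encoded.matrix()
    rf = fit_preliminary_rf(X, encoded.labels, n_trees, max_depth, seed)
    raw = compute_mean_abs_shap(rf, X)
    imp = normalize_importance(raw)
    return compute_feature_weights(
        imp, encoded.feature_order, lambda_, gamma_, raw_importance=raw
    )
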