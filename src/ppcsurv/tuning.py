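"""Cross-validated hyperparameter search.

The objective is the mean validation AUROC over k stratified folds, with
the fold partition fixed by a seed shared across every trial so that trials
are comparable.  The searcher draws configurations from a declared space by
seeded random sampling and returns the argmax trial together with a full
trial log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .hybrid import PipelineConfig, train_hybrid
from .schema import LABEL_COLUMN, Schema, default_schema

__all__ = ["SearchSpace", "Trial", "crossval_objective", "search_hyperparams"]

# search dimension -> (config section, field) of PipelineConfig
_DIMENSIONS: dict[str, tuple[str | None, str]] = {
    "batch_size": ("training", "batch_size"),
    "learning_rate": ("training", "learning_rate"),
    "loss_kind": ("training", "loss_kind"),
    "focal_alpha": ("training", "focal_alpha"),
    "focal_gamma": ("training", "focal_gamma"),
    "dropout": ("encoder", "dropout"),
    "hidden1": ("encoder", "hidden1"),
    "hidden2": ("encoder", "hidden2"),
    "embedding_dim": ("encoder", "embedding_dim"),
    "n_trees": ("rf_head", "n_trees"),
    "max_depth": ("rf_head", "max_depth"),
    "lambda_": (None, "lambda_"),
    "gamma_": (None, "gamma_"),
}


@dataclass(frozen=True)
class SearchSpace:
    """Ranges (low, high) tuples or choice lists per tunable dimension.

    A two-element tuple of numbers is a uniform range (log-uniform for
    ``learning_rate``); a list is a categorical choice.  Every dimension must
    name a known pipeline-config field.
    """

    dimensions: Mapping[str, Any] = field(default_factory=dict)
    n_trials: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in self.dimensions:
            if name not in _DIMENSIONS:
                raise ValueError(f"unknown search dimension {name!r}")

    def sample(self, rng: np.random.Generator) -> dict[str, Any]:
        out = {}
        for name, spec in self.dimensions.items():
            # a 2-tuple of numbers is a range; any list is a choice set
            if isinstance(spec, tuple) and len(spec) == 2 and all(
                isinstance(v, (int, float)) and not isinstance(v, bool) for v in spec
            ):
                lo, hi = spec
                if name == "learning_rate":
                    out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                elif isinstance(lo, int) and isinstance(hi, int):
                    out[name] = int(rng.integers(lo, hi + 1))
                else:
                    out[name] = float(rng.uniform(lo, hi))
            else:
                choices = list(spec)
                out[name] = choices[int(rng.integers(0, len(choices)))]
        return out


def apply_overrides(config: PipelineConfig, overrides: Mapping[str, Any]) -> PipelineConfig:
    """Return a PipelineConfig with the named dimensions replaced."""
    enc, tr, rf = config.encoder, config.training, config.rf_head
    top: dict[str, Any] = {}
    for name, value in overrides.items():
        section, attr = _DIMENSIONS[name]
        if section == "encoder":
            enc = replace(enc, **{attr: value})
        elif section == "training":
            tr = replace(tr, **{attr: value})
        elif section == "rf_head":
            rf = replace(rf, **{attr: value})
        else:
            top[attr] = value
    return replace(config, encoder=enc, training=tr, rf_head=rf, **top)


def crossval_objective(
    config: PipelineConfig,
    table: pd.DataFrame,
    k: int = 5,
    fold_seed: int = 0,
    schema: Schema | None = None,
) -> float:
    """Mean held-out-fold AUROC of the full pipeline over k stratified folds.

    Folds are fixed by ``fold_seed`` independently of the trial config.  A
    fold whose validation part contains a single class is an error.
    """
    schema = schema or default_schema()
    y = table[LABEL_COLUMN].to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
    aucs = []
    for train_idx, val_idx in skf.split(np.zeros(len(y)), y):
        fold_train = table.iloc[train_idx]
        fold_val = table.iloc[val_idx]
        if np.unique(fold_val[LABEL_COLUMN]).size < 2:
            raise ValueError("validation fold contains a single class")
        model = train_hybrid(fold_train, config, schema, val_table=fold_val)
        probs = model.predict_proba(fold_val)
        aucs.append(float(roc_auc_score(fold_val[LABEL_COLUMN], probs)))
    return float(np.mean(aucs))


@dataclass
class Trial:
    number: int
    overrides: dict[str, Any]
    objective: float


def search_hyperparams(
    space: SearchSpace,
    table: pd.DataFrame,
    base_config: PipelineConfig | None = None,
    k: int = 5,
    schema: Schema | None = None,
) -> tuple[PipelineConfig, list[Trial]]:
    """Randomized search maximizing the cross-validated AUROC.

    Returns the best configuration and the complete trial log.  The trial
    sequence is a deterministic function of the space's seed.
    """
    base_config = base_config or PipelineConfig()
    rng = np.random.default_rng(space.seed)
    trials: list[Trial] = []
    failures: list[str] = []
    for t in range(space.n_trials):
        overrides = space.sample(rng)
        config = apply_overrides(base_config, overrides)
        try:
            obj = crossval_objective(config, table, k=k, fold_seed=space.seed, schema=schema)
        except (ValueError, RuntimeError) as exc:  # log and continue
            failures.append(f"trial {t}: {exc}")
            continue
        trials.append(Trial(t, overrides, obj))
    if not trials:
        raise RuntimeError(
            "all search trials failed: " + "; ".join(failures[:5])
        )
    best = max(trials, key=lambda tr: tr.objective)
    return apply_overrides(base_config, best.overrides), trials
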