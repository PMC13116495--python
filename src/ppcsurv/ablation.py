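"""Four-arm ablation of the hybrid pipeline.

Arms: ``full`` (importance weighting + imbalance suite), ``no_shap``
(lambda forced to 0), ``no_imbalance`` (plain loss, plain sampler,
unbalanced forest, fixed 0.5 threshold) and ``baseline`` (both removals).
All arms of one seed share the same train/test split; per-arm metrics are
averaged over seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import split_cohort
from .hybrid import PipelineConfig, train_hybrid
from .metrics import METRIC_NAMES, MetricsReport, compute_metrics
from .schema import LABEL_COLUMN, Schema, default_schema

__all__ = ["AblationResult", "ARM_NAMES", "run_ablation"]

ARM_NAMES = ("full", "no_shap", "no_imbalance", "baseline")


@dataclass
class AblationResult:
    """Mean metric per arm, plus per-seed detail and failure flags."""

    mean: pd.DataFrame  # index: arm, columns: the seven metrics
    per_seed: pd.DataFrame  # columns: arm, seed, metrics...
    failed_arms: list[tuple[str, int, str]]

    @property
    def complete(self) -> bool:
        return not self.failed_arms

    def metric(self, arm: str, name: str) -> float:
        return float(self.mean.loc[arm, name])


def _arm_configs(base: PipelineConfig) -> dict[str, PipelineConfig]:
    return {
        "full": base,
        "no_shap": base.without_shap(),
        "no_imbalance": base.without_imbalance(),
        "baseline": base.baseline(),
    }


def run_ablation(
    table: pd.DataFrame,
    seeds: Sequence[int],
    base_config: PipelineConfig | None = None,
    test_fraction: float = 0.2,
    schema: Schema | None = None,
) -> AblationResult:
    """Train and evaluate all four arms for each seed.

    Each seed fixes one stratified train/test split and one set of model
    seeds shared by the four arms, so arm differences are attributable to
    the removed components alone.  A failing arm is recorded and skipped
    rather than aborting the study.
    """
    if len(seeds) == 0:
        raise ValueError("at least one seed is required")
    base_config = base_config or PipelineConfig()
    schema = schema or default_schema()
    rows = []
    failed: list[tuple[str, int, str]] = []
    for seed in seeds:
        train, test = split_cohort(table, test_fraction, stratified=True, seed=seed)
        seeded = replace(
            base_config,
            seed=seed,
            encoder=replace(base_config.encoder, seed=seed),
            training=replace(base_config.training, seed=seed),
            rf_head=replace(base_config.rf_head, seed=seed),
        )
        for arm, config in _arm_configs(seeded).items():
            try:
                model = train_hybrid(train, config, schema)
                probs = model.predict_proba(test)
                preds = model.predict(test)
                rep = compute_metrics(test[LABEL_COLUMN].to_numpy(), preds, probs)
            except (ValueError, RuntimeError) as exc:
                failed.append((arm, int(seed), str(exc)))
                continue
            rows.append({"arm": arm, "seed": int(seed), **rep.as_dict()})
    per_seed = pd.DataFrame(rows)
    mean = (
        per_seed.groupby("arm")[list(METRIC_NAMES)].mean().reindex(list(ARM_NAMES))
        if len(per_seed)
        else pd.DataFrame(columns=list(METRIC_NAMES))
    )
    return AblationResult(mean=mean, per_seed=per_seed, failed_arms=failed)
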