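"""Model-bundle persistence.

A trained :class:`~ppcsurv.hybrid.HybridModel` is saved as a directory:
``model.json`` (configs, normalization statistics, importance weights,
threshold, normal ranges — everything human-auditable), ``encoder.npz``
(encoder parameters) and ``rf_head.joblib`` (the forest head).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import joblib
import numpy as np

from .encoder import EncoderConfig, TabularEncoder, TrainingConfig
from .hybrid import HybridModel, PipelineConfig, RFHeadConfig
from .preprocess import NormalizationStats
from .schema import NormalRange, default_schema
from .weighting import ImportanceWeights

__all__ = ["save_model", "load_model"]


def save_model(model: HybridModel, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ranges = {}
    for spec in model.schema:
        if spec.normal_range is not None:
            from .schema import range_key_for

            key = range_key_for(spec.name)
            if key is not None:
                nr = spec.normal_range
                ranges[key] = {
                    "low": nr.low,
                    "high": nr.high,
                    "low_inclusive": nr.low_inclusive,
                    "high_inclusive": nr.high_inclusive,
                }
    meta = {
        "threshold": model.threshold,
        "config": asdict(model.config),
        "norm_stats": {"mean": model.norm_stats.mean, "sd": model.norm_stats.sd},
        "weights": {
            "feature_names": list(model.weights.feature_names),
            "raw_importance": model.weights.raw_importance.tolist(),
            "imp": model.weights.imp.tolist(),
            "lambda_": model.weights.lambda_,
            "gamma_": model.weights.gamma_,
            "w": model.weights.w.tolist(),
        },
        "normal_ranges": ranges,
        "encoder": {
            "n_numeric": model.encoder.n_numeric,
            "cardinalities": list(model.encoder.cardinalities),
            "config": asdict(model.encoder.config),
        },
    }
    (path / "model.json").write_text(json.dumps(meta, indent=2))
    np.savez(path / "encoder.npz", **model.encoder.params)
    joblib.dump(model.rf_head, path / "rf_head.joblib")


def load_model(path) -> HybridModel:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    ranges = {
        k: NormalRange(v["low"], v["high"], v["low_inclusive"], v["high_inclusive"])
        for k, v in meta["normal_ranges"].items()
    }
    schema = default_schema(ranges)
    cfg_raw = meta["config"]
    config = PipelineConfig(
        encoder=EncoderConfig(**cfg_raw["encoder"]),
        training=TrainingConfig(**cfg_raw["training"]),
        rf_head=RFHeadConfig(**cfg_raw["rf_head"]),
        **{
            k: v
            for k, v in cfg_raw.items()
            if k not in ("encoder", "training", "rf_head")
        },
    )
    enc_meta = meta["encoder"]
    encoder = TabularEncoder(
        enc_meta["n_numeric"],
        enc_meta["cardinalities"],
        EncoderConfig(**enc_meta["config"]),
    )
    with np.load(path / "encoder.npz") as npz:
        encoder.params = {k: npz[k].copy() for k in npz.files}
    wmeta = meta["weights"]
    weights = ImportanceWeights(
        tuple(wmeta["feature_names"]),
        np.asarray(wmeta["raw_importance"]),
        np.asarray(wmeta["imp"]),
        wmeta["lambda_"],
        wmeta["gamma_"],
        np.asarray(wmeta["w"]),
    )
    stats = NormalizationStats(meta["norm_stats"]["mean"], meta["norm_stats"]["sd"])
    rf = joblib.load(path / "rf_head.joblib")
    return HybridModel(
        schema=schema,
        norm_stats=stats,
        weights=weights,
        encoder=encoder,
        rf_head=rf,
        threshold=meta["threshold"],
        config=config,
    )
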