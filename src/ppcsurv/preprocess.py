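"""Continuous-feature normalization and categorical encoding.

Continuous inputs are z-scored with statistics fit on the training split
only; categorical levels are mapped to stable integer indices declared by
the schema (booleans to {0, 1}).  Unknown levels are schema violations, not
an "other" bucket, and missing values are rejected rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import derive_bins
from .schema import LABEL_COLUMN, Schema, SchemaError

__all__ = [
    "NormalizationStats",
    "fit_normalization",
    "apply_normalization",
    "encode_categoricals",
    "decode_categoricals",
    "EncodedCohort",
    "encode_cohort",
]


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature mean/sd of the numeric columns, fit on training data."""

    mean: dict[str, float]
    sd: dict[str, float]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for name, mu in self.mean.items():
            out[name] = (out[name].astype(float) - mu) / self.sd[name]
        return out


def fit_normalization(train: pd.DataFrame, schema: Schema) -> NormalizationStats:
    """Estimate z-scoring statistics on the training split.

    Uses the population (ddof=0) standard deviation so that transforming the
    training data itself yields exactly unit variance.  A zero-variance
    feature is an error naming the feature.
    """
    if len(train) == 0:
        raise ValueError("cannot fit normalization on an empty table")
    mean, sd = {}, {}
    for name in schema.numeric:
        v = train[name].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise SchemaError(f"missing values in numeric feature {name}")
        mu, s = float(v.mean()), float(v.std(ddof=0))
        if s <= 0.0:
            raise ValueError(f"feature {name!r} has zero variance on the training split")
        mean[name], sd[name] = mu, s
    return NormalizationStats(mean, sd)


def apply_normalization(table: pd.DataFrame, stats: NormalizationStats) -> pd.DataFrame:
    return stats.transform(table)


def _level_index(schema: Schema, name: str) -> dict[str, int]:
    return {level: i for i, level in enumerate(schema[name].level_set)}


def encode_categoricals(table: pd.DataFrame, schema: Schema) -> pd.DataFrame:
    """Map categorical values to schema level indices and booleans to {0, 1}.

    The mapping is invertible (:func:`decode_categoricals`); a level absent
    from the schema's level_set raises :class:`SchemaError`.
    """
    out = table.copy()
    for name in schema.categorical:
        idx = _level_index(schema, name)
        values = out[name].astype(str)
        unknown = ~values.isin(idx)
        if unknown.any():
            bad = values[unknown].iloc[0]
            raise SchemaError(f"feature {name!r} contains unknown level {bad!r}")
        out[name] = values.map(idx).astype(np.int64)
    for name in schema.boolean:
        out[name] = out[name].astype(bool).astype(np.int64)
    return out


def decode_categoricals(encoded: pd.DataFrame, schema: Schema) -> pd.DataFrame:
    """Inverse of :func:`encode_categoricals`."""
    out = encoded.copy()
    for name in schema.categorical:
        levels = schema[name].level_set
        codes = out[name].to_numpy(dtype=np.int64)
        if codes.min() < 0 or codes.max() >= len(levels):
            raise SchemaError(f"feature {name!r} contains an out-of-range code")
        out[name] = np.array(levels, dtype=object)[codes]
    for name in schema.boolean:
        out[name] = out[name].astype(bool)
    return out


@dataclass
class EncodedCohort:
    """Model-ready view of a cohort.

    ``numeric`` holds the z-scored continuous block (n x d_num), ``codes``
    the integer level codes of categorical + boolean features (n x d_cat;
    booleans are treated as 2-level categoricals so every feature has a
    weightable embedding), ``labels`` the binary outcome when present.
    ``feature_order`` is numeric names followed by code names and matches the
    column order used for importance vectors and input weights.
    """

    numeric: np.ndarray
    codes: np.ndarray
    numeric_names: tuple[str, ...]
    code_names: tuple[str, ...]
    cardinalities: tuple[int, ...]
    labels: np.ndarray | None
    index: pd.Index

    @property
    def feature_order(self) -> tuple[str, ...]:
        return self.numeric_names + self.code_names

    @property
    def n(self) -> int:
        return self.numeric.shape[0]

    def matrix(self) -> np.ndarray:
        """Flat (n, d) float matrix: z-scored numerics then level codes."""
        return np.hstack([self.numeric, self.codes.astype(float)])


def encode_cohort(
    table: pd.DataFrame,
    schema: Schema,
    stats: NormalizationStats,
    refresh_bins: bool = True,
) -> EncodedCohort:
    """Normalize, re-derive bin columns, and index-code a cohort table.

    The derived bins (Age_1, BMI_1, Anesthesia_time_1) are regenerated from
    their source numerics rather than trusted from the input.
    """
    if refresh_bins:
        table = derive_bins(table)
    encoded = encode_categoricals(table, schema)
    encoded = apply_normalization(encoded, stats)
    numeric_names = schema.numeric
    code_names = schema.categorical + schema.boolean
    cards = tuple(
        len(schema[n].level_set) if schema[n].kind == "categorical" else 2
        for n in code_names
    )
    labels = None
    if LABEL_COLUMN in encoded.columns:
        labels = encoded[LABEL_COLUMN].to_numpy(dtype=np.int64)
    return EncodedCohort(
        numeric=encoded[list(numeric_names)].to_numpy(dtype=np.float64),
        codes=encoded[list(code_names)].to_numpy(dtype=np.int64),
        numeric_names=numeric_names,
        code_names=code_names,
        cardinalities=cards,
        labels=labels,
        index=table.index,
    )
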