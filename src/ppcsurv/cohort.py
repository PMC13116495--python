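"""Synthetic postoperative cohort generator.

Real postoperative EMR extracts of this kind are access-restricted, so the
package ships a class-conditional simulator that reproduces the *structure*
of such a cohort: ~20% PPC prevalence, cases that are older, undergo longer
and more invasive (open, emergency) surgery, and show more postoperative
physiologic instability (tachycardia, desaturation, fever, anemia, pain) and
more nursing-note symptom indicators than controls.

Generation order: labels are assigned first with an exact positive count of
``round(n * prevalence)``; numeric features are then drawn class-conditionally
from truncated normal distributions inside physiologic hard bounds;
categoricals from class-conditional multinomials; the derived bin columns
(Age_1, BMI_1, Anesthesia_time_1) and the seven judge flags are deterministic
functions of the sampled values; the three symptom booleans are
label-dependent Bernoulli draws (they summarize nursing notes, not vitals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (
    LABEL_COLUMN,
    Schema,
    SYMPTOM_COLUMNS,
    default_schema,
    derive_judge_flags_frame,
)

__all__ = [
    "NumericEffect",
    "CategoricalEffect",
    "SymptomEffect",
    "CohortConfig",
    "paperlike_profile",
    "separable_profile",
    "make_config",
    "generate_cohort",
    "split_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_cohort_parquet",
    "read_cohort_parquet",
    "STRONG_FEATURES",
]


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations."""


class DegenerateSplitError(ValueError):
    """Raised when a requested split cannot hold at least one patient per class."""


@dataclass(frozen=True)
class NumericEffect:
    """Class-conditional truncated-normal parameters for one numeric feature.

    Controls are drawn from ``TN(mean, sd)`` inside the schema's hard bounds;
    cases from ``TN(mean + case_shift, sd)``.
    """

    mean: float
    sd: float
    case_shift: float = 0.0


@dataclass(frozen=True)
class CategoricalEffect:
    """Class-conditional multinomial over a categorical feature's levels."""

    probs_control: Mapping[str, float]
    probs_case: Mapping[str, float]


@dataclass(frozen=True)
class SymptomEffect:
    """Label-dependent Bernoulli rates for a nursing-note symptom boolean."""

    p_control: float
    p_case: float


Effect = NumericEffect | CategoricalEffect | SymptomEffect

# Columns computed from other columns, never drawn directly.
DERIVED_COLUMNS = (
    "Age_1",
    "BMI_1",
    "Anesthesia_time_1",
    "BMI",
    "SBP_judge",
    "DBP_judge",
    "BT_judge",
    "RR_judge",
    "PR_judge",
    "SpO2_judge",
    "NRS_judge",
)

# Paired min/max vitals whose ordering is enforced after sampling.
_MINMAX_PAIRS = (
    ("SBP_min", "SBP_max"),
    ("DBP_min", "DBP_max"),
    ("BT_min", "BT_max"),
    ("RR_min", "RR_max"),
    ("PR_min", "PR_max"),
)


def paperlike_profile() -> dict[str, Effect]:
    """Default moderate-separation profile (well-specified models reach
    AUROC around 0.8 on held-out data).

    The three strongest planted numeric effects, in units of the control
    standard deviation, are Min_SpO2, Anesthesia_time and PR_max
    (:data:`STRONG_FEATURES`).
    """
    return {
        # demographics / anthropometrics
        "Age": NumericEffect(52.0, 15.0, 5.5),
        "Stature": NumericEffect(163.0, 9.0, 0.0),
        "Weight": NumericEffect(65.0, 12.0, 1.0),
        # surgery / anesthesia
        "Anesthesia_time": NumericEffect(115.0, 55.0, 36.0),
        # labs & vitals (postoperative min/max summaries)
        "Hb_min": NumericEffect(12.8, 1.7, -0.55),
        "SBP_max": NumericEffect(136.0, 16.0, 2.5),
        "SBP_min": NumericEffect(101.0, 12.0, -1.0),
        "DBP_max": NumericEffect(83.0, 10.0, 1.0),
        "DBP_min": NumericEffect(63.0, 9.0, -1.0),
        "BT_max": NumericEffect(37.2, 0.45, 0.12),
        "BT_min": NumericEffect(36.3, 0.30, 0.0),
        "RR_max": NumericEffect(18.0, 2.4, 0.65),
        "RR_min": NumericEffect(13.5, 1.8, 0.0),
        "PR_max": NumericEffect(88.0, 13.0, 8.0),
        "PR_min": NumericEffect(66.0, 9.0, 0.0),
        "Min_SpO2": NumericEffect(96.6, 1.8, -1.15),
        "NRS_avg": NumericEffect(2.7, 1.2, 0.30),
        # categoricals
        "Gender": CategoricalEffect({"F": 0.52, "M": 0.48}, {"F": 0.46, "M": 0.54}),
        "Surgical_code_site": CategoricalEffect(
            {
                "gallbladder": 0.32,
                "appendix": 0.22,
                "stomach": 0.12,
                "colorectal": 0.20,
                "liver": 0.06,
                "pancreas": 0.04,
                "other": 0.04,
            },
            {
                "gallbladder": 0.27,
                "appendix": 0.18,
                "stomach": 0.16,
                "colorectal": 0.20,
                "liver": 0.09,
                "pancreas": 0.06,
                "other": 0.04,
            },
        ),
        "Sugical_code_approach": CategoricalEffect(
            {"laparoscopic": 0.72, "open": 0.23, "robotic": 0.05},
            {"laparoscopic": 0.62, "open": 0.33, "robotic": 0.05},
        ),
        "Diagnostic_code": CategoricalEffect(
            {
                "benign_gi": 0.45,
                "inflammatory": 0.25,
                "malignancy_gi": 0.15,
                "hpb_malignancy": 0.08,
                "other": 0.07,
            },
            {
                "benign_gi": 0.37,
                "inflammatory": 0.22,
                "malignancy_gi": 0.18,
                "hpb_malignancy": 0.14,
                "other": 0.09,
            },
        ),
        "Is_emergency": CategoricalEffect(
            {"elective": 0.85, "emergency": 0.15}, {"elective": 0.73, "emergency": 0.27}
        ),
        "Is_smoke": CategoricalEffect(
            {"never": 0.60, "former": 0.25, "current": 0.15},
            {"never": 0.54, "former": 0.27, "current": 0.19},
        ),
        "Is_drinker": CategoricalEffect({"no": 0.65, "yes": 0.35}, {"no": 0.61, "yes": 0.39}),
        "Is_acivity_free": CategoricalEffect(
            {"independent": 0.85, "assisted": 0.12, "dependent": 0.03},
            {"independent": 0.79, "assisted": 0.16, "dependent": 0.05},
        ),
        "L_tube": CategoricalEffect({"no": 0.92, "yes": 0.08}, {"no": 0.86, "yes": 0.14}),
        "Has_medical_history": CategoricalEffect(
            {
                "none": 0.45,
                "cardiovascular": 0.20,
                "pulmonary": 0.08,
                "metabolic": 0.17,
                "multiple": 0.10,
            },
            {
                "none": 0.37,
                "cardiovascular": 0.22,
                "pulmonary": 0.13,
                "metabolic": 0.16,
                "multiple": 0.12,
            },
        ),
        # nursing-note symptom indicators
        "Systemic_infection_symptoms": SymptomEffect(0.06, 0.14),
        "Bronchial_secretion_symptoms": SymptomEffect(0.08, 0.17),
        "Respiratory_symptoms": SymptomEffect(0.07, 0.16),
    }


#: The three largest planted numeric effects of the paper-like profile
#: (standardized case shifts of ~0.62-0.65 control SDs each; every other
#: numeric effect is at most ~0.37 SD).
STRONG_FEATURES: tuple[str, str, str] = ("Min_SpO2", "Anesthesia_time", "PR_max")


def separable_profile() -> dict[str, Effect]:
    """Near-separable profile for pipeline smoke tests (AUROC > 0.95)."""
    prof = paperlike_profile()
    prof.update(
        {
            "Age": NumericEffect(50.0, 13.0, 15.0),
            "Anesthesia_time": NumericEffect(100.0, 45.0, 110.0),
            "PR_max": NumericEffect(85.0, 11.0, 24.0),
            "Min_SpO2": NumericEffect(97.0, 1.4, -4.2),
            "Hb_min": NumericEffect(13.2, 1.5, -2.2),
            "RR_max": NumericEffect(17.0, 2.0, 4.5),
            "BT_max": NumericEffect(37.0, 0.40, 0.7),
            "NRS_avg": NumericEffect(2.4, 1.0, 1.5),
            "Systemic_infection_symptoms": SymptomEffect(0.03, 0.55),
            "Bronchial_secretion_symptoms": SymptomEffect(0.03, 0.60),
            "Respiratory_symptoms": SymptomEffect(0.03, 0.58),
        }
    )
    return prof


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one synthetic cohort draw."""

    n_patients: int
    prevalence: float = 0.2
    effect_profile: Mapping[str, Effect] = field(default_factory=paperlike_profile)
    seed: int = 0
    schema: Schema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError("prevalence must lie strictly in (0, 1)")
        for name, eff in self.effect_profile.items():
            if name not in self.schema:
                raise ConfigurationError(f"effect_profile names unknown feature {name!r}")
            spec = self.schema[name]
            if isinstance(eff, NumericEffect):
                if spec.kind != "numeric":
                    raise ConfigurationError(f"{name} is not numeric")
                if eff.sd <= 0:
                    raise ConfigurationError(f"{name}: sd must be positive")
            elif isinstance(eff, CategoricalEffect):
                if spec.kind != "categorical":
                    raise ConfigurationError(f"{name} is not categorical")
                for probs in (eff.probs_control, eff.probs_case):
                    if set(probs) - set(spec.level_set):
                        raise ConfigurationError(f"{name}: unknown level in profile")
                    total = sum(probs.values())
                    if not np.isclose(total, 1.0, atol=1e-6):
                        raise ConfigurationError(f"{name}: probabilities sum to {total}")
            elif isinstance(eff, SymptomEffect):
                if spec.kind != "boolean":
                    raise ConfigurationError(f"{name} is not boolean")
                for p in (eff.p_control, eff.p_case):
                    if not (0.0 <= p <= 1.0):
                        raise ConfigurationError(f"{name}: rate {p} outside [0, 1]")

    def with_shift(self, feature: str, case_shift: float) -> "CohortConfig":
        """Return a copy with one numeric feature's case shift replaced."""
        prof = dict(self.effect_profile)
        eff = prof[feature]
        if not isinstance(eff, NumericEffect):
            raise ConfigurationError(f"{feature} has no numeric effect")
        prof[feature] = replace(eff, case_shift=case_shift)
        return replace(self, effect_profile=prof)


def make_config(
    n_patients: int,
    prevalence: float = 0.2,
    preset: str = "paperlike",
    seed: int = 0,
) -> CohortConfig:
    """Convenience constructor for the two shipped presets."""
    if preset == "paperlike":
        profile = paperlike_profile()
    elif preset == "separable":
        profile = separable_profile()
    else:
        raise ConfigurationError(f"unknown preset {preset!r}")
    return CohortConfig(n_patients, prevalence, profile, seed)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _bin_age(age: np.ndarray) -> np.ndarray:
    edges = [30, 40, 50, 60, 70, 80]
    labels = np.array(["19-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+"])
    return labels[np.searchsorted(edges, age, side="right")]


def _bin_bmi(bmi: np.ndarray) -> np.ndarray:
    edges = [18.5, 25.0, 30.0]
    labels = np.array(["underweight", "normal", "overweight", "obese"])
    return labels[np.searchsorted(edges, bmi, side="right")]


def _bin_anesthesia(minutes: np.ndarray) -> np.ndarray:
    edges = [60, 120, 180, 240]
    labels = np.array(["<1h", "1-2h", "2-3h", "3-4h", ">=4h"])
    return labels[np.searchsorted(edges, minutes, side="right")]


def derive_bins(table: pd.DataFrame) -> pd.DataFrame:
    """(Re)compute the derived bin columns from their source numerics."""
    out = table.copy()
    out["Age_1"] = _bin_age(out["Age"].to_numpy(dtype=float))
    out["BMI_1"] = _bin_bmi(out["BMI"].to_numpy(dtype=float))
    out["Anesthesia_time_1"] = _bin_anesthesia(
        out["Anesthesia_time"].to_numpy(dtype=float)
    )
    return out


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw one synthetic cohort.

    Returns a DataFrame with the 41 schema columns plus the ``ppc`` label,
    indexed by patient id, with exactly ``round(n_patients * prevalence)``
    positive labels.  Identical config + seed reproduces an identical table.
    """
    schema = config.schema
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_pos = int(round(n * config.prevalence))
    if n_pos == 0 or n_pos == n:
        raise ConfigurationError(
            f"prevalence {config.prevalence} yields a single-class cohort at n={n}"
        )
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1
    case = labels == 1

    cols: dict[str, np.ndarray] = {}
    profile = config.effect_profile

    for spec in schema:
        name = spec.name
        if name in DERIVED_COLUMNS:
            continue
        eff = profile.get(name)
        if spec.kind == "numeric":
            if not isinstance(eff, NumericEffect):
                raise ConfigurationError(f"no numeric effect configured for {name}")
            lo, hi = spec.hard_bounds
            v = np.empty(n, dtype=float)
            v[~case] = _truncnorm(rng, eff.mean, eff.sd, lo, hi, int((~case).sum()))
            v[case] = _truncnorm(
                rng, eff.mean + eff.case_shift, eff.sd, lo, hi, int(case.sum())
            )
            if spec.integer:
                v = np.round(v)
            cols[name] = v
        elif spec.kind == "categorical":
            if not isinstance(eff, CategoricalEffect):
                raise ConfigurationError(f"no categorical effect configured for {name}")
            levels = np.array(spec.level_set)
            out = np.empty(n, dtype=object)
            for mask, probs in ((~case, eff.probs_control), (case, eff.probs_case)):
                p = np.array([probs.get(l, 0.0) for l in spec.level_set], dtype=float)
                p = p / p.sum()
                out[mask] = rng.choice(levels, size=int(mask.sum()), p=p)
            cols[name] = out
        elif spec.kind == "boolean" and name in SYMPTOM_COLUMNS:
            if not isinstance(eff, SymptomEffect):
                raise ConfigurationError(f"no symptom effect configured for {name}")
            p = np.where(case, eff.p_case, eff.p_control)
            cols[name] = rng.random(n) < p

    # enforce min <= max for paired vitals (swap inversions; marginals are
    # chosen far enough apart that inversions are rare)
    for lo_col, hi_col in _MINMAX_PAIRS:
        lo_v, hi_v = cols[lo_col], cols[hi_col]
        inverted = lo_v > hi_v
        lo_v[inverted], hi_v[inverted] = hi_v[inverted].copy(), lo_v[inverted].copy()

    table = pd.DataFrame(cols)
    table["BMI"] = table["Weight"] / (table["Stature"] / 100.0) ** 2
    table["BMI"] = table["BMI"].clip(*schema["BMI"].hard_bounds)
    table = derive_bins(table)
    flags = derive_judge_flags_frame(table, schema)
    for flag in flags.columns:
        table[flag] = flags[flag]
    table[LABEL_COLUMN] = labels
    table = table[list(schema.feature_names) + [LABEL_COLUMN]]
    table.index.name = "patient_id"
    return table


def split_cohort(
    table: pd.DataFrame,
    test_fraction: float,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint train/test partition of a cohort.

    Stratified splitting preserves the class fraction within one patient of
    exact proportionality per class.  Reproducible under a fixed seed.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ConfigurationError("test_fraction must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(table)
    if stratified:
        labels = table[LABEL_COLUMN].to_numpy()
        test_idx = []
        for value in np.unique(labels):
            members = np.flatnonzero(labels == value)
            k = int(round(len(members) * test_fraction))
            if k == 0 or k == len(members):
                raise DegenerateSplitError(
                    f"class {value} has too few patients ({len(members)}) for a "
                    f"{test_fraction:.0%} stratified test split"
                )
            test_idx.append(rng.choice(members, size=k, replace=False))
        test_mask = np.zeros(n, dtype=bool)
        test_mask[np.concatenate(test_idx)] = True
    else:
        k = int(round(n * test_fraction))
        if k == 0 or k == n:
            raise DegenerateSplitError("test split would be empty or exhaustive")
        test_mask = np.zeros(n, dtype=bool)
        test_mask[rng.choice(n, size=k, replace=False)] = True
    return table.loc[~test_mask], table.loc[test_mask]


# -- tabular interchange ----------------------------------------------------


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort as CSV (full float precision, booleans as True/False)."""
    table.to_csv(path, index=True)


def read_cohort_csv(path, schema: Schema | None = None) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort_csv`."""
    schema = schema or default_schema()
    table = pd.read_csv(path, index_col=0)
    for name in schema.boolean:
        if name in table.columns and table[name].dtype != bool:
            table[name] = table[name].map(
                {"True": True, "False": False, True: True, False: False, 1: True, 0: False}
            )
    return table


def write_cohort_parquet(table: pd.DataFrame, path) -> None:
    table.to_parquet(path)


def read_cohort_parquet(path) -> pd.DataFrame:
    return pd.read_parquet(path)
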