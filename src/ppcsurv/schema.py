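"""Feature schema for the postoperative pulmonary complication (PPC) cohort.

The cohort is a flat table of 41 patient-level features collected during the
postoperative surveillance window (surgery to discharge): demographics and
anthropometrics, surgery/anesthesia descriptors, min/max summaries of vital
signs, boolean "judge" flags marking vitals outside their configured normal
range, and nursing-note-derived symptom indicators.  The binary outcome
column ``ppc`` marks patients flagged for pulmonary-complication
surveillance.

Normal ranges are shipped as editable configuration (see
:func:`load_normal_ranges` / :data:`DEFAULT_NORMAL_RANGES`); only the SpO2
cut-off (< 95%) is a hard clinical anchor, the remainder are standard adult
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureSpec",
    "NormalRange",
    "Schema",
    "ValidationIssue",
    "ValidationReport",
    "default_schema",
    "derive_judge_flags",
    "derive_judge_flags_frame",
    "validate_schema",
    "LABEL_COLUMN",
    "FEATURE_NAMES",
    "DEFAULT_NORMAL_RANGES",
    "load_normal_ranges",
    "dump_normal_ranges",
]

LABEL_COLUMN = "ppc"


class SchemaError(ValueError):
    """Raised when data violate the declared feature schema."""


class DataQualityError(ValueError):
    """Raised when a value falls outside its physiologic hard bounds."""


@dataclass(frozen=True)
class NormalRange:
    """Closed (or half-open) interval of clinically normal values.

    ``low``/``high`` bound the normal interval; inclusivity is configurable so
    one-sided rules such as "abnormal iff SpO2 < 95" (low inclusive) and
    "abnormal iff NRS >= 4" (high exclusive) are representable.
    """

    low: float
    high: float
    low_inclusive: bool = True
    high_inclusive: bool = True

    def contains(self, value: float) -> bool:
        above = value >= self.low if self.low_inclusive else value > self.low
        below = value <= self.high if self.high_inclusive else value < self.high
        return bool(above and below)

    def violation(self, value: float) -> str | None:
        """Return 'low'/'high' for an out-of-range value, else None."""
        if (value < self.low) or (not self.low_inclusive and value == self.low):
            return "low"
        if (value > self.high) or (not self.high_inclusive and value == self.high):
            return "high"
        return None

    def threshold_text(self, side: str) -> str:
        if side == "low":
            return f"<{self.low:g}" if self.low_inclusive else f"<={self.low:g}"
        return f">{self.high:g}" if self.high_inclusive else f">={self.high:g}"


@dataclass(frozen=True)
class FeatureSpec:
    """Declared type and constraints of one cohort column."""

    name: str
    kind: str  # "numeric" | "categorical" | "boolean"
    units: str = ""
    level_set: tuple[str, ...] = ()
    normal_range: NormalRange | None = None
    hard_bounds: tuple[float, float] | None = None
    integer: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical", "boolean"):
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name}")
        if self.kind == "categorical" and not self.level_set:
            raise SchemaError(f"categorical feature {self.name} needs a level_set")
        if self.normal_range is not None and self.hard_bounds is not None:
            lo, hi = self.hard_bounds
            if not (lo <= self.normal_range.low and self.normal_range.high <= hi):
                raise SchemaError(
                    f"normal_range of {self.name} must lie inside hard_bounds"
                )


# Judge flag -> columns it summarizes and the range key it uses.  A flag is
# true iff ANY of its summary columns falls outside the configured range.
JUDGE_MAP: dict[str, tuple[tuple[str, ...], str]] = {
    "SBP_judge": (("SBP_max", "SBP_min"), "SBP"),
    "DBP_judge": (("DBP_max", "DBP_min"), "DBP"),
    "BT_judge": (("BT_max", "BT_min"), "BT"),
    "RR_judge": (("RR_max", "RR_min"), "RR"),
    "PR_judge": (("PR_max", "PR_min"), "PR"),
    "SpO2_judge": (("Min_SpO2",), "SpO2"),
    "NRS_judge": (("NRS_avg",), "NRS"),
}

# Default adult normal ranges; SpO2 abnormal iff < 95, NRS abnormal iff >= 4,
# all others two-sided inclusive intervals.
DEFAULT_NORMAL_RANGES: dict[str, NormalRange] = {
    "SBP": NormalRange(90.0, 140.0),
    "DBP": NormalRange(60.0, 90.0),
    "BT": NormalRange(36.0, 38.0),
    "RR": NormalRange(12.0, 20.0),
    "PR": NormalRange(60.0, 100.0),
    "SpO2": NormalRange(95.0, 100.0),
    "NRS": NormalRange(0.0, 4.0, high_inclusive=False),
}

# map vital column -> range key (SBP_max -> "SBP", ...)
_RANGE_KEY_OF_COLUMN: dict[str, str] = {}
for _flag, (_cols, _key) in JUDGE_MAP.items():
    for _c in _cols:
        _RANGE_KEY_OF_COLUMN[_c] = _key


def range_key_for(column: str) -> str | None:
    """Range key ('SBP', 'SpO2', ...) monitored for a vital column, if any."""
    return _RANGE_KEY_OF_COLUMN.get(column)


def _numeric(name, units, lo, hi, range_key=None, ranges=None, integer=False):
    nr = None
    if range_key is not None:
        nr = (ranges or DEFAULT_NORMAL_RANGES)[range_key]
    return FeatureSpec(name, "numeric", units, (), nr, (lo, hi), integer)


def default_schema(
    normal_ranges: Mapping[str, NormalRange] | None = None,
) -> "Schema":
    """Build the canonical 41-feature schema.

    Column names (including the spellings ``Sugical_code_approach`` and
    ``Is_acivity_free``) follow the source EMR export verbatim.
    """
    r = dict(DEFAULT_NORMAL_RANGES)
    if normal_ranges:
        r.update(normal_ranges)

    cat = lambda name, levels: FeatureSpec(name, "categorical", "", tuple(levels))
    boo = lambda name: FeatureSpec(name, "boolean")

    specs = [
        _numeric("Age", "years", 19, 105, integer=True),
        cat("Age_1", ("19-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")),
        cat("Gender", ("F", "M")),
        cat(
            "Surgical_code_site",
            ("gallbladder", "appendix", "stomach", "colorectal", "liver", "pancreas", "other"),
        ),
        cat("Sugical_code_approach", ("laparoscopic", "open", "robotic")),
        cat(
            "Diagnostic_code",
            ("benign_gi", "inflammatory", "malignancy_gi", "hpb_malignancy", "other"),
        ),
        _numeric("Anesthesia_time", "min", 10, 1000),
        cat("Anesthesia_time_1", ("<1h", "1-2h", "2-3h", "3-4h", ">=4h")),
        cat("Is_emergency", ("elective", "emergency")),
        _numeric("Stature", "cm", 130, 210),
        _numeric("Weight", "kg", 30, 200),
        _numeric("BMI", "kg/m2", 10, 60),
        cat("BMI_1", ("underweight", "normal", "overweight", "obese")),
        cat("Is_smoke", ("never", "former", "current")),
        cat("Is_drinker", ("no", "yes")),
        cat("Is_acivity_free", ("independent", "assisted", "dependent")),
        cat("L_tube", ("no", "yes")),
        _numeric("Hb_min", "g/dL", 3, 22),
        _numeric("SBP_max", "mmHg", 40, 260, "SBP", r),
        _numeric("SBP_min", "mmHg", 40, 260, "SBP", r),
        _numeric("DBP_max", "mmHg", 20, 200, "DBP", r),
        _numeric("DBP_min", "mmHg", 20, 200, "DBP", r),
        _numeric("BT_max", "degC", 33, 43, "BT", r),
        _numeric("BT_min", "degC", 33, 43, "BT", r),
        _numeric("RR_max", "breaths/min", 4, 60, "RR", r),
        _numeric("RR_min", "breaths/min", 4, 60, "RR", r),
        _numeric("PR_max", "beats/min", 20, 250, "PR", r),
        _numeric("PR_min", "beats/min", 20, 250, "PR", r),
        _numeric("Min_SpO2", "%", 50, 100, "SpO2", r),
        boo("SBP_judge"),
        boo("DBP_judge"),
        boo("BT_judge"),
        boo("RR_judge"),
        boo("PR_judge"),
        boo("SpO2_judge"),
        boo("NRS_judge"),
        cat(
            "Has_medical_history",
            ("none", "cardiovascular", "pulmonary", "metabolic", "multiple"),
        ),
        _numeric("NRS_avg", "score", 0, 10, "NRS", r),
        boo("Systemic_infection_symptoms"),
        boo("Bronchial_secretion_symptoms"),
        boo("Respiratory_symptoms"),
    ]
    return Schema(specs)


class Schema:
    """Ordered collection of :class:`FeatureSpec` with lookup helpers."""

    def __init__(self, specs: Iterable[FeatureSpec]):
        specs = list(specs)
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")
        self.specs: tuple[FeatureSpec, ...] = tuple(specs)
        self._by_name = {s.name: s for s in specs}

    def __iter__(self):
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> FeatureSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown feature {name!r}") from None

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def names_of_kind(self, kind: str) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs if s.kind == kind)

    @property
    def numeric(self) -> tuple[str, ...]:
        return self.names_of_kind("numeric")

    @property
    def categorical(self) -> tuple[str, ...]:
        return self.names_of_kind("categorical")

    @property
    def boolean(self) -> tuple[str, ...]:
        return self.names_of_kind("boolean")


FEATURE_NAMES: tuple[str, ...] = default_schema().feature_names

SYMPTOM_COLUMNS = (
    "Systemic_infection_symptoms",
    "Bronchial_secretion_symptoms",
    "Respiratory_symptoms",
)


def derive_judge_flags(
    record: Mapping[str, float], schema: Schema
) -> dict[str, bool]:
    """Derive the seven abnormality flags from a patient's vital summaries.

    A flag is true iff any of its summary vitals falls outside the configured
    normal range (SpO2 one-sided: abnormal iff below the lower threshold; pain
    one-sided: abnormal iff at or above the upper threshold).

    Raises :class:`DataQualityError` if a referenced vital lies outside its
    physiologic hard bounds.
    """
    flags: dict[str, bool] = {}
    for flag, (cols, _key) in JUDGE_MAP.items():
        abnormal = False
        for col in cols:
            spec = schema[col]
            value = float(record[col])
            if spec.hard_bounds is not None:
                lo, hi = spec.hard_bounds
                if not (lo <= value <= hi):
                    raise DataQualityError(
                        f"{col}={value} outside hard bounds [{lo}, {hi}]"
                    )
            if spec.normal_range is not None and not spec.normal_range.contains(value):
                abnormal = True
        flags[flag] = abnormal
    return flags


def derive_judge_flags_frame(table: pd.DataFrame, schema: Schema) -> pd.DataFrame:
    """Vectorized :func:`derive_judge_flags` over a cohort table."""
    out = {}
    for flag, (cols, _key) in JUDGE_MAP.items():
        abnormal = np.zeros(len(table), dtype=bool)
        for col in cols:
            spec = schema[col]
            v = table[col].to_numpy(dtype=float)
            lo, hi = spec.hard_bounds
            bad = (v < lo) | (v > hi)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise DataQualityError(
                    f"{col}={v[i]} outside hard bounds [{lo}, {hi}] (row {i})"
                )
            nr = spec.normal_range
            above = (v >= nr.low) if nr.low_inclusive else (v > nr.low)
            below = (v <= nr.high) if nr.high_inclusive else (v < nr.high)
            abnormal |= ~(above & below)
        out[flag] = abnormal
    return pd.DataFrame(out, index=table.index)


@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # missing_column | extra_column | missing_value | out_of_bounds
    #          | bad_level | bad_boolean | flag_inconsistency | bad_label
    column: str
    row: object | None = None
    detail: str = ""


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __len__(self) -> int:
        return len(self.issues)

    def of_kind(self, kind: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.kind == kind]

    def to_json_lines(self) -> str:
        import json

        return "\n".join(
            json.dumps(
                {"kind": i.kind, "column": i.column, "row": i.row, "detail": i.detail}
            )
            for i in self.issues
        )


def validate_schema(
    table: pd.DataFrame,
    schema: Schema,
    check_label: bool = True,
    check_flags: bool = True,
) -> ValidationReport:
    """Validate a cohort table against the schema.

    Reports (never raises): missing/extra columns, missing values (any missing
    value is a hard failure — the pipeline performs no imputation),
    out-of-bounds numerics, unknown categorical levels, non-boolean flag
    values, and judge flags inconsistent with a re-derivation from the vitals.
    """
    report = ValidationReport()
    expected = set(schema.feature_names)
    present = set(table.columns)
    for name in schema.feature_names:
        if name not in present:
            report.issues.append(ValidationIssue("missing_column", name))
    for name in table.columns:
        if name not in expected and name != LABEL_COLUMN:
            report.issues.append(ValidationIssue("extra_column", name))
    if check_label and LABEL_COLUMN not in present:
        report.issues.append(ValidationIssue("missing_column", LABEL_COLUMN))

    usable = [s for s in schema if s.name in present]
    for spec in usable:
        col = table[spec.name]
        na = col.isna()
        for row in table.index[na]:
            report.issues.append(ValidationIssue("missing_value", spec.name, row))
        ok_rows = ~na
        if spec.kind == "numeric" and spec.hard_bounds is not None:
            v = pd.to_numeric(col[ok_rows], errors="coerce")
            lo, hi = spec.hard_bounds
            bad = v.isna() | (v < lo) | (v > hi)
            for row in v.index[bad]:
                report.issues.append(
                    ValidationIssue(
                        "out_of_bounds", spec.name, row, f"value={col[row]!r}"
                    )
                )
        elif spec.kind == "categorical":
            levels = set(spec.level_set)
            bad = ~col[ok_rows].astype(str).isin(levels)
            for row in col[ok_rows].index[bad]:
                report.issues.append(
                    ValidationIssue("bad_level", spec.name, row, f"value={col[row]!r}")
                )
        elif spec.kind == "boolean":
            vals = col[ok_rows]
            bad = ~vals.isin([True, False, 0, 1])
            for row in vals.index[bad]:
                report.issues.append(
                    ValidationIssue(
                        "bad_boolean", spec.name, row, f"value={col[row]!r}"
                    )
                )

    if check_label and LABEL_COLUMN in present:
        lab = table[LABEL_COLUMN]
        bad = ~lab.isin([0, 1, True, False])
        for row in lab.index[bad]:
            report.issues.append(
                ValidationIssue("bad_label", LABEL_COLUMN, row, f"value={lab[row]!r}")
            )

    vital_cols = {c for cols, _key in JUDGE_MAP.values() for c in cols}
    flags_available = all(f in present for f in JUDGE_MAP) and all(
        c in present for c in vital_cols
    )
    if check_flags and flags_available and not report.issues:
        derived = derive_judge_flags_frame(table, schema)
        for flag in JUDGE_MAP:
            observed = table[flag].astype(bool)
            mism = observed.to_numpy() != derived[flag].to_numpy()
            for row in table.index[mism]:
                report.issues.append(
                    ValidationIssue(
                        "flag_inconsistency",
                        flag,
                        row,
                        f"stored={bool(observed[row])}, derived={bool(derived.loc[row, flag])}",
                    )
                )
    return report


def load_normal_ranges(path) -> dict[str, NormalRange]:
    """Load normal-range configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for key, spec in raw.items():
        out[key] = NormalRange(
            float(spec["low"]),
            float(spec["high"]),
            bool(spec.get("low_inclusive", True)),
            bool(spec.get("high_inclusive", True)),
        )
    return out


def dump_normal_ranges(ranges: Mapping[str, NormalRange], path) -> None:
    raw = {
        k: {
            "low": v.low,
            "high": v.high,
            "low_inclusive": v.low_inclusive,
            "high_inclusive": v.high_inclusive,
        }
        for k, v in ranges.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
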