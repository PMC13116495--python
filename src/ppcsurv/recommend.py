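"""Deterministic nursing-surveillance recommendation engine.

Maps a patient's assessed abnormalities and predicted PPC risk to a
predefined ontology of 12 surveillance actions, emitting structured
action-evidence-rationale records; validates any such record against the
ontology and the normal-range configuration (labels: correct,
evidence_mismatch, unnecessary_action); scores patients on the 5/1 scheme
with half-up rounded per-patient bins; and builds the itemized prompt used
when an external language model is slotted in instead of the rule engine.

The engine is sound by construction: every record it emits is labelled
``correct`` by its own validator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .schema import (
    LABEL_COLUMN,
    Schema,
    SYMPTOM_COLUMNS,
    SchemaError,
    default_schema,
    validate_schema,
)

__all__ = [
    "ActionOntology",
    "Finding",
    "Evidence",
    "Recommendation",
    "ValidationLabel",
    "load_ontology",
    "default_ontology",
    "assess_patient",
    "recommend_actions",
    "validate_recommendation",
    "score_patient",
    "summarize_scores",
    "serialize_recommendations",
    "deserialize_recommendations",
    "build_llm_prompt",
    "recommend_cohort",
]

RISK_EVIDENCE = "predicted_risk"

# Display names and units for evidence rendering.
_DISPLAY = {
    "SBP_max": ("Blood pressure (SBP)", "mmHg"),
    "SBP_min": ("Blood pressure (SBP)", "mmHg"),
    "DBP_max": ("Blood pressure (DBP)", "mmHg"),
    "DBP_min": ("Blood pressure (DBP)", "mmHg"),
    "BT_max": ("Body temperature", "°C"),
    "BT_min": ("Body temperature", "°C"),
    "RR_max": ("Respiratory rate", "breaths/min"),
    "RR_min": ("Respiratory rate", "breaths/min"),
    "PR_max": ("Pulse rate", "beats/min"),
    "PR_min": ("Pulse rate", "beats/min"),
    "Min_SpO2": ("Oxygen saturation", "%"),
    "NRS_avg": ("Pain score (NRS)", "points"),
    "Systemic_infection_symptoms": ("Systemic infection symptoms", ""),
    "Bronchial_secretion_symptoms": ("Bronchial secretion symptoms", ""),
    "Respiratory_symptoms": ("Respiratory symptoms", ""),
}

_DIRECTION_WORD = {"high": "Elevated", "low": "Low", "present": "Documented"}


@dataclass(frozen=True)
class ActionSpec:
    id: int
    text: str
    tier: str  # "basic" | "elevated"
    evidence: frozenset[str]


@dataclass(frozen=True)
class ActionOntology:
    """The 12-action ontology plus per-risk default actions."""

    actions: tuple[ActionSpec, ...]
    defaults: Mapping[str, tuple[int, ...]]

    def __post_init__(self):
        ids = sorted(a.id for a in self.actions)
        if ids != list(range(1, 13)):
            raise ValueError("ontology must contain exactly actions 1..12")
        basic = {a.id for a in self.actions if a.tier == "basic"}
        if 10 not in basic:
            raise ValueError("action 10 (early ambulation) must be tier basic")

    def __getitem__(self, action_id: int) -> ActionSpec:
        for a in self.actions:
            if a.id == action_id:
                return a
        raise KeyError(f"unknown action id {action_id}")

    def validate_features(self, schema: Schema) -> None:
        for a in self.actions:
            unknown = a.evidence - set(schema.feature_names)
            if unknown:
                raise SchemaError(
                    f"action {a.id} cites unknown features {sorted(unknown)}"
                )


def load_ontology(path) -> ActionOntology:
    """Load an action ontology from YAML configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    actions = tuple(
        ActionSpec(
            int(a["id"]), str(a["text"]), str(a["tier"]), frozenset(a.get("evidence") or ())
        )
        for a in raw["actions"]
    )
    defaults = {k: tuple(v) for k, v in raw.get("defaults", {}).items()}
    return ActionOntology(actions, defaults)


def default_ontology() -> ActionOntology:
    """The ontology shipped with the package."""
    ref = resources.files("ppcsurv") / "data" / "ontology.yaml"
    with resources.as_file(ref) as path:
        return load_ontology(path)


@dataclass(frozen=True)
class Finding:
    """One abnormal observation: a vital outside its normal range or a
    documented symptom indicator."""

    feature: str
    value: float | bool
    threshold: str  # e.g. ">140", "<95", "present"
    direction: str  # "high" | "low" | "present"


def assess_patient(
    record: Mapping[str, object], schema: Schema | None = None
) -> list[Finding]:
    """List a patient's abnormal findings.

    One finding per numeric feature outside its configured normal range and
    per true symptom boolean, each carrying the observed value and the
    violated threshold.  Features without a normal range (age, labs without
    a judge flag, anthropometrics) never generate findings.
    """
    schema = schema or default_schema()
    findings: list[Finding] = []
    for spec in schema:
        if spec.name not in record:
            continue
        value = record[spec.name]
        if spec.kind == "numeric" and spec.normal_range is not None:
            v = float(value)
            if spec.hard_bounds is not None:
                lo, hi = spec.hard_bounds
                if not (lo <= v <= hi):
                    raise SchemaError(
                        f"{spec.name}={v} outside hard bounds [{lo}, {hi}]"
                    )
            side = spec.normal_range.violation(v)
            if side is not None:
                findings.append(
                    Finding(
                        spec.name,
                        v,
                        spec.normal_range.threshold_text(side),
                        "high" if side == "high" else "low",
                    )
                )
        elif spec.name in SYMPTOM_COLUMNS and bool(value):
            findings.append(Finding(spec.name, True, "present", "present"))
    return findings


@dataclass(frozen=True)
class Evidence:
    """The patient information justifying an action, in structured form."""

    feature: str  # a schema feature, or RISK_EVIDENCE for tier defaults
    value: float | bool | str
    threshold: str

    def render(self) -> str:
        if self.feature == RISK_EVIDENCE:
            return f"Predicted PPC risk: {self.value}"
        name, units = _DISPLAY.get(self.feature, (self.feature, ""))
        if isinstance(self.value, bool):
            return f"{name}: {'present' if self.value else 'absent'}"
        unit_sfx = f" {units}" if units else ""
        return f"{name}: {self.value:g}{unit_sfx} (threshold {self.threshold})"


@dataclass(frozen=True)
class Recommendation:
    """One action-evidence-rationale record for one patient."""

    patient_id: object
    action_ids: tuple[int, ...]
    action_texts: tuple[str, ...]
    evidence: Evidence
    rationale: str
    risk: str  # "high" | "low"

    def to_triple(self) -> dict:
        return {
            "action": list(self.action_texts),
            "evidence": self.evidence.render(),
            "rationale": self.rationale,
        }


def _rationale(action: ActionSpec, finding: Finding | None, risk: str) -> str:
    if finding is None:
        if action.tier == "basic":
            return (
                "Predicted risk is low with no abnormal findings; basic "
                "preventive care such as early ambulation is sufficient."
            )
        return (
            "Predicted PPC risk is high, so baseline oxygenation and "
            "vital-sign surveillance should be intensified even before "
            "overt abnormalities appear."
        )
    name, _units = _DISPLAY.get(finding.feature, (finding.feature, ""))
    word = _DIRECTION_WORD[finding.direction]
    subject = f"{word} {name.lower()}"
    purpose = {
        1: "warrants close observation of breathing effort and pattern",
        2: "warrants monitoring for cough and breathing discomfort",
        3: "warrants assessment of sputum characteristics",
        4: "requires continued oxygen-saturation monitoring",
        5: "requires monitoring and potential physician notification",
        6: "warrants serial temperature measurement",
        7: "warrants monitoring for systemic signs such as chills and flushing",
        8: "warrants regular reassessment of pain level and pattern",
        9: "should prompt encouraging the patient to report pain changes",
        11: "is a status change the physician should be informed about",
        12: "may justify a follow-up chest X-ray, to be discussed with the doctor",
    }[action.id]
    return f"{subject} {purpose}."


def recommend_actions(
    findings: Sequence[Finding],
    risk_label: str,
    ontology: ActionOntology | None = None,
    patient_id: object = None,
) -> list[Recommendation]:
    """Deterministic action recommendations for one patient.

    For each finding, every action whose admissible-evidence set contains
    the finding's feature is emitted with that finding as evidence.  High
    risk additionally emits the tier-elevated monitoring defaults (actions
    4 and 5) justified by the predicted risk itself, unless already emitted
    for a concrete finding; low risk with no findings yields only the basic
    tier (action 10).
    """
    if risk_label not in ("high", "low"):
        raise ValueError("risk_label must be 'high' or 'low'")
    ontology = ontology or default_ontology()
    recs: list[Recommendation] = []
    emitted: set[int] = set()
    for finding in findings:
        for action in ontology.actions:
            if finding.feature in action.evidence:
                recs.append(
                    Recommendation(
                        patient_id,
                        (action.id,),
                        (action.text,),
                        Evidence(finding.feature, finding.value, finding.threshold),
                        _rationale(action, finding, risk_label),
                        risk_label,
                    )
                )
                emitted.add(action.id)
    default_ids = ontology.defaults.get(risk_label, ())
    for aid in default_ids:
        action = ontology[aid]
        if risk_label == "low" and (findings or action.tier != "basic"):
            continue
        if aid in emitted:
            continue
        recs.append(
            Recommendation(
                patient_id,
                (action.id,),
                (action.text,),
                Evidence(RISK_EVIDENCE, risk_label, "risk-tier default"),
                _rationale(action, None, risk_label),
                risk_label,
            )
        )
    return recs


@dataclass(frozen=True)
class ValidationLabel:
    """Outcome of checking one record: correct (5 points) or one of the two
    failure modes (1 point)."""

    label: str  # "correct" | "evidence_mismatch" | "unnecessary_action"

    @property
    def score(self) -> int:
        return 5 if self.label == "correct" else 1


def _evidence_abnormal(evidence: Evidence, schema: Schema) -> bool:
    spec = schema[evidence.feature]
    if spec.kind == "boolean":
        return bool(evidence.value)
    if spec.normal_range is None:
        return False
    return spec.normal_range.violation(float(evidence.value)) is not None


def validate_recommendation(
    rec: Recommendation,
    ontology: ActionOntology | None = None,
    schema: Schema | None = None,
) -> ValidationLabel:
    """Deterministic evidence-consistency check of one record.

    ``unnecessary_action``: the cited value is within its normal range (or a
    cited symptom is absent).  ``evidence_mismatch``: the value is abnormal
    but the feature is not in the action's admissible-evidence set.
    ``correct`` otherwise.  Risk-tier evidence is correct iff the action is
    the declared default for that risk level.  A record listing several
    actions is correct only if every action is.
    """
    ontology = ontology or default_ontology()
    schema = schema or default_schema()
    ev = rec.evidence
    if ev.feature == RISK_EVIDENCE:
        defaults = set(ontology.defaults.get(str(ev.value), ()))
        for aid in rec.action_ids:
            ontology[aid]  # raises KeyError on unknown actions
            if aid not in defaults:
                return ValidationLabel("unnecessary_action")
        return ValidationLabel("correct")
    if ev.feature not in schema:
        raise SchemaError(f"evidence cites unknown feature {ev.feature!r}")
    if not _evidence_abnormal(ev, schema):
        return ValidationLabel("unnecessary_action")
    for aid in rec.action_ids:
        action = ontology[aid]
        if ev.feature not in action.evidence:
            return ValidationLabel("evidence_mismatch")
    return ValidationLabel("correct")


def score_patient(labels: Sequence[ValidationLabel]) -> int:
    """Per-patient score bin: mean of 5/1 action scores, rounded half-up."""
    if len(labels) == 0:
        raise ValueError("at least one validated action is required")
    mean = float(np.mean([l.score for l in labels]))
    return int(min(5, max(1, int(np.floor(mean + 0.5)))))


def summarize_scores(bins: Iterable[int]) -> pd.DataFrame:
    """Five-bin frequency table (scores 5..1 plus total)."""
    bins = list(bins)
    if any(b < 1 or b > 5 for b in bins):
        raise ValueError("score bins must lie in 1..5")
    counts = {f"score_{s}": sum(1 for b in bins if b == s) for s in (5, 4, 3, 2, 1)}
    counts["total"] = len(bins)
    return pd.DataFrame([counts])


# -- serialization ----------------------------------------------------------


class _TripleModel(BaseModel):
    action: list[str] = Field(min_length=1)
    evidence: str
    rationale: str
    action_ids: list[int]
    evidence_detail: dict


class _PatientDocModel(BaseModel):
    patient_id: int | str | None
    risk: str
    recommendations: list[_TripleModel]


def serialize_recommendations(recs: Sequence[Recommendation]) -> str:
    """Serialize one patient's records as a schema-validated JSON document.

    The document keeps the human-readable action/evidence/rationale triple
    (the EMR-facing payload) alongside machine-readable detail so the
    round-trip is lossless.
    """
    if not recs:
        raise ValueError("no recommendations to serialize")
    pids = {r.patient_id for r in recs}
    risks = {r.risk for r in recs}
    if len(pids) != 1 or len(risks) != 1:
        raise ValueError("one document covers exactly one patient and risk label")
    doc = {
        "patient_id": recs[0].patient_id,
        "risk": recs[0].risk,
        "recommendations": [
            {
                **r.to_triple(),
                "action_ids": list(r.action_ids),
                "evidence_detail": {
                    "feature": r.evidence.feature,
                    "value": r.evidence.value,
                    "threshold": r.evidence.threshold,
                },
            }
            for r in recs
        ],
    }
    model = _PatientDocModel.model_validate(doc)  # raises on structural errors
    return json.dumps(model.model_dump(), indent=2)


def deserialize_recommendations(document: str) -> list[Recommendation]:
    """Inverse of :func:`serialize_recommendations`."""
    model = _PatientDocModel.model_validate(json.loads(document))
    recs = []
    for t in model.recommendations:
        d = t.evidence_detail
        recs.append(
            Recommendation(
                model.patient_id,
                tuple(t.action_ids),
                tuple(t.action),
                Evidence(d["feature"], d["value"], d["threshold"]),
                t.rationale,
                model.risk,
            )
        )
    return recs


# -- LLM prompt construction ------------------------------------------------

_ROLE_SENTENCE = "You are a highly precise nursing surveillance support system."

_PROMPT_FIELDS = (
    ("Age", "Age: {:.0f} years"),
    ("Gender", "Sex: {}"),
    ("Surgical_code_site", "Surgical site: {}"),
    ("Sugical_code_approach", "Surgical approach: {}"),
    ("Anesthesia_time", "Anesthesia time: {:.0f} minutes"),
    ("Hb_min", "Hb_min: {:g}"),
    ("SBP_max", "SBP_max: {:g}"),
    ("SBP_min", "SBP_min: {:g}"),
    ("DBP_max", "DBP_max: {:g}"),
    ("DBP_min", "DBP_min: {:g}"),
    ("BT_max", "BT_max: {:g}"),
    ("BT_min", "BT_min: {:g}"),
    ("RR_max", "RR_max: {:g}"),
    ("RR_min", "RR_min: {:g}"),
    ("PR_max", "PR_max: {:g}"),
    ("PR_min", "PR_min: {:g}"),
    ("Min_SpO2", "Min_SpO2: {:g}"),
    ("NRS_avg", "NRS_avg: {:g}"),
    ("Systemic_infection_symptoms", "Systemic infection symptoms: {}"),
    ("Bronchial_secretion_symptoms", "Bronchial secretion symptoms: {}"),
    ("Respiratory_symptoms", "Respiratory symptoms: {}"),
)


def build_llm_prompt(record: Mapping[str, object], risk_label: str) -> str:
    """Deterministic prompt for an external language model.

    Role/format instruction, itemized patient-status bullets, and a JSON
    output directive; the rule engine's validator and scorer can then be
    applied to the external model's parsed output.
    """
    if risk_label not in ("high", "low"):
        raise ValueError("risk_label must be 'high' or 'low'")
    lines = [
        _ROLE_SENTENCE
        + f" This patient was at a {risk_label} risk of developing pulmonary"
        " complications. Provide a list of nursing interventions for the"
        " patient below and output the evidence and theoretical explanations"
        " in JSON format.",
        "",
        "Patient status:",
    ]
    for feature, template in _PROMPT_FIELDS:
        if feature not in record:
            continue
        value = record[feature]
        if isinstance(value, (bool, np.bool_)):
            value = "TRUE" if value else "FALSE"
        lines.append("- " + template.format(value))
    lines += [
        "",
        'Respond only with JSON of the form {"action": [...], "evidence":'
        ' "...", "rationale": "..."}.',
    ]
    return "\n".join(lines)


def recommend_cohort(
    table: pd.DataFrame,
    risk_labels: Sequence[str],
    ontology: ActionOntology | None = None,
    schema: Schema | None = None,
) -> tuple[list[list[Recommendation]], pd.DataFrame]:
    """Run assessment, recommendation, validation and scoring per patient.

    Returns per-patient recommendation lists and a summary frame (patient
    id, risk, n_actions, n_correct, score bin).
    """
    ontology = ontology or default_ontology()
    schema = schema or default_schema()
    report = validate_schema(table, schema, check_label=False)
    if not report.ok:
        raise SchemaError(f"cohort fails validation ({len(report)} issues)")
    all_recs: list[list[Recommendation]] = []
    rows = []
    for (pid, record), risk in zip(table.iterrows(), risk_labels):
        findings = assess_patient(record, schema)
        recs = recommend_actions(findings, risk, ontology, patient_id=pid)
        labels = [validate_recommendation(r, ontology, schema) for r in recs]
        score = score_patient(labels) if labels else 5
        rows.append(
            {
                "patient_id": pid,
                "risk": risk,
                "n_actions": len(recs),
                "n_correct": sum(1 for l in labels if l.label == "correct"),
                "score": score,
            }
        )
        all_recs.append(recs)
    return all_recs, pd.DataFrame(rows)
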