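"""Rule-engine recommendations, evidence validation, scoring and prompts."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppcsurv import (
    Evidence,
    Recommendation,
    assess_patient,
    build_llm_prompt,
    default_ontology,
    deserialize_recommendations,
    recommend_actions,
    score_patient,
    serialize_recommendations,
    summarize_scores,
    validate_recommendation,
)
from ppcsurv.recommend import RISK_EVIDENCE, ValidationLabel

# The published case-study patient block.
CASE_PATIENT = {
    "Hb_min": 11.7, "SBP_max": 151, "SBP_min": 113, "DBP_max": 130,
    "DBP_min": 58, "BT_max": 37.1, "BT_min": 36.4, "RR_max": 20,
    "RR_min": 20, "PR_max": 64, "PR_min": 46, "Min_SpO2": 95,
    "NRS_avg": 2.125,
    "Systemic_infection_symptoms": False,
    "Bronchial_secretion_symptoms": False,
    "Respiratory_symptoms": False,
}


def test_ontology_structure():
    onto = default_ontology()
    assert sorted(a.id for a in onto.actions) == list(range(1, 13))
    assert onto[10].tier == "basic"
    assert onto[5].text == "Verify intervals for vital signs and SpO2 monitoring"
    assert "Min_SpO2" in onto[4].evidence
    onto.validate_features(__import__("ppcsurv").default_schema())


def test_case_patient_findings(schema):
    findings = {f.feature: f for f in assess_patient(CASE_PATIENT, schema)}
    assert "SBP_max" in findings
    assert findings["SBP_max"].direction == "high"
    assert findings["SBP_max"].threshold == ">140"
    # temperature, respiration, saturation and pain are all within range
    for normal in ("BT_max", "BT_min", "RR_max", "RR_min", "Min_SpO2", "NRS_avg"):
        assert normal not in findings
    # documented symptom booleans are all false
    assert not any(f.feature.endswith("symptoms") for f in findings.values())


def test_low_spo2_finding_threshold(schema):
    record = {**CASE_PATIENT, "Min_SpO2": 90}
    findings = {f.feature: f for f in assess_patient(record, schema)}
    assert findings["Min_SpO2"].threshold == "<95"


def test_all_normal_patient_has_no_findings(schema):
    record = {
        **CASE_PATIENT, "SBP_max": 120, "SBP_min": 110, "DBP_max": 80,
        "DBP_min": 70, "PR_max": 80, "PR_min": 66,
    }
    assert assess_patient(record, schema) == []


def test_high_risk_recommendations_include_verify_intervals(schema):
    findings = assess_patient(CASE_PATIENT, schema)
    recs = recommend_actions(findings, "high", patient_id=1)
    by_action = {r.action_ids[0]: r for r in recs}
    assert 5 in by_action
    sbp_recs = [r for r in recs if r.action_ids[0] == 5 and r.evidence.feature == "SBP_max"]
    assert sbp_recs and sbp_recs[0].evidence.value == 151
    assert "Blood pressure (SBP): 151" in sbp_recs[0].evidence.render()
    assert 4 in by_action  # monitoring default / vital-justified


def test_spo2_finding_triggers_saturation_monitoring(schema):
    record = {**CASE_PATIENT, "Min_SpO2": 90, "SBP_max": 120, "SBP_min": 110,
              "DBP_max": 80, "DBP_min": 70, "PR_max": 80, "PR_min": 66}
    findings = assess_patient(record, schema)
    recs = recommend_actions(findings, "high")
    actions = {r.action_ids[0] for r in recs}
    assert 4 in actions and 1 in actions and 2 in actions


def test_low_risk_no_findings_gets_basic_tier_only():
    recs = recommend_actions([], "low", patient_id=7)
    assert [r.action_ids for r in recs] == [(10,)]
    assert recs[0].evidence.feature == RISK_EVIDENCE
    with pytest.raises(ValueError):
        recommend_actions([], "medium")


def test_high_risk_no_findings_gets_monitoring_defaults():
    recs = recommend_actions([], "high")
    assert sorted(r.action_ids[0] for r in recs) == [4, 5]


# -- validator: the three published case labels -----------------------------

def _rec(action_id, feature, value, threshold):
    onto = default_ontology()
    return Recommendation(
        patient_id=0,
        action_ids=(action_id,),
        action_texts=(onto[action_id].text,),
        evidence=Evidence(feature, value, threshold),
        rationale="",
        risk="high",
    )


@pytest.mark.parametrize(
    "action_id, feature, value, threshold, expected",
    [
        (5, "SBP_max", 151.0, ">140", "correct"),
        (6, "BT_max", 37.1, "", "unnecessary_action"),
        (1, "SBP_max", 151.0, ">140", "evidence_mismatch"),
    ],
)
def test_validator_reproduces_case_study_labels(action_id, feature, value, threshold, expected):
    label = validate_recommendation(_rec(action_id, feature, value, threshold))
    assert label.label == expected
    assert label.score == (5 if expected == "correct" else 1)


def test_validator_risk_default_rules():
    onto = default_ontology()
    ok = Recommendation(0, (4,), (onto[4].text,), Evidence(RISK_EVIDENCE, "high", "d"), "", "high")
    assert validate_recommendation(ok).label == "correct"
    bad = Recommendation(0, (6,), (onto[6].text,), Evidence(RISK_EVIDENCE, "high", "d"), "", "high")
    assert validate_recommendation(bad).label == "unnecessary_action"


def test_engine_is_sound_on_case_patient(schema):
    findings = assess_patient(CASE_PATIENT, schema)
    for risk in ("high", "low"):
        for rec in recommend_actions(findings, risk):
            assert validate_recommendation(rec).label == "correct"


# -- scoring ----------------------------------------------------------------

def _labels(seq):
    return [ValidationLabel("correct" if s == 5 else "evidence_mismatch") for s in seq]


@pytest.mark.parametrize(
    "scores, expected",
    [([5, 5, 5], 5), ([5, 5, 1], 4), ([1], 1), ([5, 1], 3), ([5, 1, 1], 2)],
)
def test_patient_score_binning(scores, expected):
    assert score_patient(_labels(scores)) == expected


def test_score_requires_labels():
    with pytest.raises(ValueError):
        score_patient([])


def test_summarize_scores_tallies(rng):
    bins = rng.integers(1, 6, size=200)
    table = summarize_scores(bins)
    assert int(table["total"].iloc[0]) == 200
    total = sum(int(table[f"score_{s}"].iloc[0]) for s in range(1, 6))
    assert total == 200
    for s in range(1, 6):
        assert int(table[f"score_{s}"].iloc[0]) == int(np.sum(bins == s))
    with pytest.raises(ValueError):
        summarize_scores([0, 3])


# -- serialization ----------------------------------------------------------

def test_serialized_document_has_triple_keys(schema):
    findings = assess_patient(CASE_PATIENT, schema)
    recs = recommend_actions(findings, "high", patient_id=42)
    doc = serialize_recommendations(recs)
    parsed = json.loads(doc)
    assert parsed["patient_id"] == 42
    for triple in parsed["recommendations"]:
        assert {"action", "evidence", "rationale"} <= set(triple)
        assert isinstance(triple["action"], list)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(data=st.data())
def test_serialization_round_trip(data):
    onto = default_ontology()
    n = data.draw(st.integers(1, 6))
    risk = data.draw(st.sampled_from(["high", "low"]))
    recs = []
    for _ in range(n):
        aid = data.draw(st.integers(1, 12))
        feature = data.draw(st.sampled_from(["SBP_max", "Min_SpO2", "NRS_avg", RISK_EVIDENCE]))
        value = risk if feature == RISK_EVIDENCE else data.draw(
            st.floats(0, 200, allow_nan=False)
        )
        recs.append(
            Recommendation(
                3, (aid,), (onto[aid].text,),
                Evidence(feature, value, ">x"),
                data.draw(st.text(max_size=30)), risk,
            )
        )
    back = deserialize_recommendations(serialize_recommendations(recs))
    assert back == recs


def test_serialize_rejects_mixed_patients():
    onto = default_ontology()
    a = Recommendation(1, (4,), (onto[4].text,), Evidence(RISK_EVIDENCE, "high", "d"), "", "high")
    b = Recommendation(2, (4,), (onto[4].text,), Evidence(RISK_EVIDENCE, "high", "d"), "", "high")
    with pytest.raises(ValueError):
        serialize_recommendations([a, b])


# -- prompt builder ---------------------------------------------------------

def test_prompt_contains_role_sentence_and_bullets():
    record = {"Age": 82, "Gender": "F", "Surgical_code_site": "gallbladder", **CASE_PATIENT}
    prompt = build_llm_prompt(record, "high")
    assert "You are a highly precise nursing surveillance support system." in prompt
    assert "- Age: 82 years" in prompt
    assert "- Sex: F" in prompt
    assert "- Surgical site: gallbladder" in prompt
    assert "JSON" in prompt
    assert prompt == build_llm_prompt(record, "high")  # deterministic
    assert "low risk" in build_llm_prompt(record, "low")
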