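"""Turn findings + predicted risk into validated surveillance recommendations.

The rule engine assesses which vitals violate their configured normal
ranges, maps each finding to admissible actions from the 12-action
ontology, and serializes action-evidence-rationale JSON documents.  The
validator labels each record correct / evidence_mismatch /
unnecessary_action and scores patients on the 5/1 scheme.
"""

from ppcsurv import (
    assess_patient,
    build_llm_prompt,
    default_schema,
    recommend_actions,
    score_patient,
    serialize_recommendations,
    validate_recommendation,
)

patient = {
    "Hb_min": 11.7, "SBP_max": 151, "SBP_min": 113, "DBP_max": 130,
    "DBP_min": 58, "BT_max": 37.1, "BT_min": 36.4, "RR_max": 20,
    "RR_min": 20, "PR_max": 64, "PR_min": 46, "Min_SpO2": 95,
    "NRS_avg": 2.125, "Systemic_infection_symptoms": False,
    "Bronchial_secretion_symptoms": False, "Respiratory_symptoms": False,
}

schema = default_schema()
findings = assess_patient(patient, schema)
print("findings:", [(f.feature, f.value, f.threshold) for f in findings])

recs = recommend_actions(findings, risk_label="high", patient_id=1)
labels = [validate_recommendation(r) for r in recs]
for rec, label in zip(recs, labels):
    print(f"[{label.label:9s}] action {rec.action_ids[0]:2d}: {rec.action_texts[0]}")
    print(f"            evidence: {rec.evidence.render()}")
print("patient score bin:", score_patient(labels))

print("\nJSON document:\n", serialize_recommendations(recs)[:400], "...")
print("\nLLM prompt (for an external model):\n", build_llm_prompt(patient, "high")[:300], "...")
# Every engine-emitted record validates as correct; the prompt builder lets
# an external language model be swapped in and judged by the same validator.
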