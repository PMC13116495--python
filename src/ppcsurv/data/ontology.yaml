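# Nursing surveillance action ontology.
#
# 12 predefined actions; `evidence` lists the cohort features whose abnormal
# findings justify the action, `tier` separates basic actions (appropriate
# for low-risk patients without findings) from elevated surveillance.
# Editable configuration: deployments may re-map evidence sets to local
# protocols without touching code.
actions:
  - id: 1
    text: "Monitor the respiratory rate and breathing pattern"
    tier: elevated
    evidence: [RR_max, RR_min, Min_SpO2, Respiratory_symptoms]
  - id: 2
    text: "Monitor cough and breathing discomfort"
    tier: elevated
    evidence: [RR_max, RR_min, Min_SpO2, Respiratory_symptoms]
  - id: 3
    text: "Monitor the characteristics of the sputum"
    tier: elevated
    evidence: [Bronchial_secretion_symptoms]
  - id: 4
    text: "Monitor oxygen saturation (SpO2)"
    tier: elevated
    evidence: [Min_SpO2, SBP_max, SBP_min, DBP_max, DBP_min, PR_max, PR_min,
               RR_max, RR_min, BT_max, BT_min]
  - id: 5
    text: "Verify intervals for vital signs and SpO2 monitoring"
    tier: elevated
    evidence: [Min_SpO2, SBP_max, SBP_min, DBP_max, DBP_min, PR_max, PR_min,
               RR_max, RR_min, BT_max, BT_min]
  - id: 6
    text: "Monitor body temperature"
    tier: elevated
    evidence: [BT_max, BT_min, Systemic_infection_symptoms]
  - id: 7
    text: "Monitor symptoms: heat sensation, chills, shivering, facial flushing"
    tier: elevated
    evidence: [BT_max, BT_min, Systemic_infection_symptoms]
  - id: 8
    text: "Monitor the level and pattern of pain"
    tier: elevated
    evidence: [NRS_avg]
  - id: 9
    text: "Encourage the patient to express their pain"
    tier: elevated
    evidence: [NRS_avg]
  - id: 10
    text: "Explain the importance of early ambulation and provide encouragement"
    tier: basic
    evidence: []
  - id: 11
    text: "Communicate with the doctor about changes in patient status"
    tier: elevated
    evidence: [SBP_max, SBP_min, DBP_max, DBP_min, BT_max, BT_min, RR_max,
               RR_min, PR_max, PR_min, Min_SpO2, NRS_avg,
               Systemic_infection_symptoms, Bronchial_secretion_symptoms,
               Respiratory_symptoms]
  - id: 12
    text: "Communicate with the doctor about the necessity of a follow-up chest X-ray"
    tier: elevated
    evidence: [SBP_max, SBP_min, DBP_max, DBP_min, BT_max, BT_min, RR_max,
               RR_min, PR_max, PR_min, Min_SpO2, NRS_avg,
               Systemic_infection_symptoms, Bronchial_secretion_symptoms,
               Respiratory_symptoms]
# Risk-tier default actions: emitted from predicted risk alone, without an
# abnormal finding.
defaults:
  high: [4, 5]
  low: [10]
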