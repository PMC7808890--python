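# Example knowledge base for an asthma hospital-visit cohort.
# allowed_items: feature-value items a clinician marked as plausibly positively
# correlated with future asthma hospital visits. interventions: recommendation
# texts linked to the actionable items (items without an entry, e.g. ethnicity,
# are allowed in rules but carry no intervention).
allowed_items:
  - ed_visits_ge_12
  - distinct_asthma_meds_ge_21
  - asthma_prescribers_ge_9
  - health_literacy_le_244
  - systemic_steroid_units_ge_25
  - ethnicity_hispanic
  - major_asthma_visits_ge_4
  - no_outpatient_visit
  - inpatient_los_gt_1p75_le_2p95
  - last_ed_visit_le_49d
interventions:
  - intervention_id: avoid_emergency_care
    item_id: ed_visits_ge_12
    text: Implement control strategies to avoid the need for emergency care
  - intervention_id: tailor_medications
    item_id: distinct_asthma_meds_ge_21
    text: Tailor prescribed asthma medications and help the patient maximize asthma control medication adherence
  - intervention_id: social_resources
    item_id: asthma_prescribers_ge_9
    text: Provide the patient with social resources to address social chaos that leads to ineffective access to health care
  - intervention_id: education_access
    item_id: health_literacy_le_244
    text: Improve education access in the area where the patient lives to help increase health literacy
  - intervention_id: tailor_medications_steroids
    item_id: systemic_steroid_units_ge_25
    text: Tailor prescribed asthma medications and help the patient maximize asthma control medication adherence
  - intervention_id: avoid_emergency_care_major_visits
    item_id: major_asthma_visits_ge_4
    text: Implement control strategies to avoid the need for emergency care
  - intervention_id: obtain_pcp
    item_id: no_outpatient_visit
    text: Help the patient obtain a primary care provider if the patient does not already have one
  - intervention_id: avoid_emergency_care_los
    item_id: inpatient_los_gt_1p75_le_2p95
    text: Implement control strategies to avoid the need for emergency care
  - intervention_id: avoid_emergency_care_recent_ed
    item_id: last_ed_visit_le_49d
    text: Implement control strategies to avoid the need for emergency care
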