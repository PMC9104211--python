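schema_version: 1
pretest_malignant: 0.831
start_age_years: 62
wtp: 100000.0
annual_discount: 0.03
cost_biopsy: 1375.0
cost_timely_treatment: 4231.0
cost_delayed_treatment: 6346.5
cost_unnecessary_biopsy: 1375.0
cost_no_action: 0.0
monthly_cost_no_tumor: 108.5
monthly_cost_localized_y1: 2148.25
monthly_cost_localized_later: 212.67
monthly_cost_metastatic_y1: 2086.42
monthly_cost_metastatic_later: 810.58
utility_no_tumor: 1.0
utility_localized: 0.75
utility_metastatic: 0.66
utility_dead: 0.0
p_non_r0: 0.0573
p_local_recurrence: 0.1075
p_metastases_no_tumor: 0.01
p_metastases_localized: 0.13
p_successful_recurrence_surgery: 0.412
excess_death_metastatic: 0.35
excess_death_localized: 0.035
tests:
- name: CEUS
  sensitivity: 0.991
  specificity: 0.805
  exam_cost: 285.0
- name: CT
  sensitivity: 0.75
  specificity: 0.72
  exam_cost: 233.0
- name: MRI
  sensitivity: 0.9
  specificity: 0.96
  exam_cost: 381.0
psa:
  pretest_malignant:
    family: beta
    mean: 0.831
    cv: 0.2
  start_age_years:
    family: fixed
    mean: 62
    cv: 0.0
  wtp:
    family: fixed
    mean: 100000.0
    cv: 0.0
  annual_discount:
    family: fixed
    mean: 0.03
    cv: 0.0
  cost_biopsy:
    family: gamma
    mean: 1375.0
    cv: 0.2
  cost_timely_treatment:
    family: gamma
    mean: 4231.0
    cv: 0.2
  cost_delayed_treatment:
    family: gamma
    mean: 6346.5
    cv: 0.2
  cost_unnecessary_biopsy:
    family: gamma
    mean: 1375.0
    cv: 0.2
  cost_no_action:
    family: fixed
    mean: 0.0
    cv: 0.0
  monthly_cost_no_tumor:
    family: gamma
    mean: 108.5
    cv: 0.2
  monthly_cost_localized_y1:
    family: gamma
    mean: 2148.25
    cv: 0.2
  monthly_cost_localized_later:
    family: gamma
    mean: 212.67
    cv: 0.2
  monthly_cost_metastatic_y1:
    family: gamma
    mean: 2086.42
    cv: 0.2
  monthly_cost_metastatic_later:
    family: gamma
    mean: 810.58
    cv: 0.2
  utility_no_tumor:
    family: fixed
    mean: 1.0
    cv: 0.0
  utility_localized:
    family: beta
    mean: 0.75
    cv: 0.2
  utility_metastatic:
    family: beta
    mean: 0.66
    cv: 0.2
  utility_dead:
    family: fixed
    mean: 0.0
    cv: 0.0
  p_non_r0:
    family: beta
    mean: 0.0573
    cv: 0.2
  p_local_recurrence:
    family: beta
    mean: 0.1075
    cv: 0.2
  p_metastases_no_tumor:
    family: beta
    mean: 0.01
    cv: 0.2
  p_metastases_localized:
    family: beta
    mean: 0.13
    cv: 0.2
  p_successful_recurrence_surgery:
    family: beta
    mean: 0.412
    cv: 0.2
  excess_death_metastatic:
    family: beta
    mean: 0.35
    cv: 0.2
  excess_death_localized:
    family: beta
    mean: 0.035
    cv: 0.2
  sensitivity_ceus:
    family: beta
    mean: 0.991
    cv: 0.04764907034923472
  specificity_ceus:
    family: beta
    mean: 0.805
    cv: 0.2
  exam_cost_ceus:
    family: gamma
    mean: 285.0
    cv: 0.2
  sensitivity_ct:
    family: beta
    mean: 0.75
    cv: 0.2
  specificity_ct:
    family: beta
    mean: 0.72
    cv: 0.2
  exam_cost_ct:
    family: gamma
    mean: 233.0
    cv: 0.2
  sensitivity_mri:
    family: beta
    mean: 0.9
    cv: 0.16666666666666663
  specificity_mri:
    family: beta
    mean: 0.96
    cv: 0.1020620726159658
  exam_cost_mri:
    family: gamma
    mean: 381.0
    cv: 0.2
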