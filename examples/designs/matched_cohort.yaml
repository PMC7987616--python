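# A complete matched-cohort study design, documenting the config schema.
#
# Exposed group: incident type-2 diabetes followed by metformin (strict
# order, same-day counts as in-order). Four controls per exposed, matched on
# age (+-1 year), sex and HbA1c (+-2 mmol/mol within the previous 735 days),
# sharing the exposed patient's index date. Cardiovascular outcomes; BMI and
# smoking at baseline. Dates are ISO-8601 or DD/MM/YYYY.

design_type: cohort            # cohort | case_control | cross_sectional

period:
  study_start: 15/01/1998
  study_end: 15/12/2019
  key_date_offset_days: 365    # added to each practice's data-quality key date
  registration_leadin_days: 365  # registration run-in before eligibility
  entry_age_min: 25
  entry_age_max: 84
  exit_age_max: 115
  sex_filter: any              # male | female | any

entities:
  - name: Type2Diabetes
    criteria: inclusion
    exposure_type: incident_only   # incident_only | incident_or_prevalent | first_after_entry
    definition: [C10F.00, C10F.11]
  - name: Metformin
    criteria: inclusion
    exposure_type: incident_only
    definition: [MFN001]
  - name: Amputation
    criteria: exclusion
    exposure_type: exclude_ever    # exclude_ever | exclude_before_index
    definition: [AMP001]
  # entities used only as outcomes / baselines / matching variables carry
  # no criteria (their exposure semantics are ignored at those stages)
  - name: IschemicHeartDisease
    definition: [IHD001]
  - name: Stroke
    definition: [STRK01]
  - name: HeartFailure
    definition: [HF0001]
  - name: HbA1c
    definition: [HBA1C01]
  - name: BMI
    definition: [BMI001]
  - name: Smoking
    definition: [SMOK00, SMOK01]

exposure_logic:
  expression: Type2Diabetes and Metformin   # and/or with parentheses; and binds tighter
  mode: strict                              # strict (order enforced) | loose

controls_required: true
# control_logic: {expression: ..., mode: ...}  # omit = unexposed is "absence of exposure"

match_criteria:
  n_controls_per_exposed: 4
  age_tolerance_years: 1
  sex_match: "yes"             # yes | any | opposite
  # registration_tolerance_days: 365
  match_ethnicity: false
  match_townsend: false
  # exposure_duration: {entity: Type2Diabetes, tolerance_days: 365}
  # baseline_conditions: [Hypertension]
  # baseline_treatments: [Aspirin]
  measurement_matches:
    - {entity: HbA1c, lookback_days: 735, value_tolerance: 2}
  exclude_outcomes_before_index: [IschemicHeartDisease, Stroke, HeartFailure]
  # exclude_events_before_index: [ObstructiveSleepApnoea]
  unmatched_policy: keep_unmatched   # keep_unmatched | drop_unmatched

outcomes: [IschemicHeartDisease, Stroke, HeartFailure]
pre_index_outcome_exclusion: true

baselines:
  - {entity: BMI, rule: latest_before_index, lookback_days: 735}
  - {entity: Smoking, rule: latest_before_index}
  # rules: latest_before_index | earliest_ever | first_after_index

seed: 20240101
# encrypt_password: never store real passwords in configs; use
#   `ehrcohort extract --encrypt-password-file` instead
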