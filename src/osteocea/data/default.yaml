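population:
  start_age: 78
  max_age: 110
  prevalent_vertebral_fraction: 0.23
  cycle_length: 0.5
run_settings:
  annual_discount_rate_costs: 0.03
  annual_discount_rate_effects: 0.03
  psa_draws: 1000
  psa_seed: 0
  wtp_threshold: 100000.0
utilities:
  multiplier_year1:
    hip: 0.7
    vertebral: 0.59
    nhnv: 0.902
  multiplier_later:
    hip: 0.8
    vertebral: 0.93
    nhnv: 1.0
costs:
  fracture_year1:
    hip: 28112.0
    vertebral: 7882.0
    nhnv: 9236.0
  hip_subsequent_annual: 9734.0
  ltc_daily: 236.0
  ltc_admission_fraction: 0.2
  monitoring:
  - resource: bmd_measurement
    unit_cost: 243.0
    events_per_year: 0.5
  - resource: physician_visit
    unit_cost: 100.0
    events_per_year: 1.0
strategies:
- name: generic_alendronate
  rr_hip: 0.62
  rr_vert: 0.62
  rr_nhnv: 0.82
  annual_drug_cost: 30.0
  admin_events: []
  max_treatment_years: 5.0
  offset_years: 2.0
  persistence_class: oral_reference
  hazard_ratio: 1.0
- name: denosumab
  rr_hip: 0.38
  rr_vert: 0.36
  rr_nhnv: 0.84
  annual_drug_cost: 1650.0
  admin_events:
  - resource: nurse_visit
    unit_cost: 42.0
    events_per_year: 2.0
  max_treatment_years: 5.0
  offset_years: 2.0
  persistence_class: injectable_hr_adjusted
  hazard_ratio: 0.5
- name: zoledronate
  rr_hip: 0.82
  rr_vert: 0.34
  rr_nhnv: 0.73
  annual_drug_cost: 1084.0
  admin_events:
  - resource: iv_injection
    unit_cost: 151.0
    events_per_year: 1.0
  max_treatment_years: 5.0
  offset_years: 2.0
  persistence_class: injectable_hr_adjusted
  hazard_ratio: 0.5
- name: risedronate
  rr_hip: 0.85
  rr_vert: 0.56
  rr_nhnv: 0.8
  annual_drug_cost: 1708.0
  admin_events: []
  max_treatment_years: 5.0
  offset_years: 2.0
  persistence_class: oral_reference
  hazard_ratio: 1.0
- name: ibandronate
  rr_hip: 1.0
  rr_vert: 0.51
  rr_nhnv: 1.0
  annual_drug_cost: 1332.0
  admin_events: []
  max_treatment_years: 5.0
  offset_years: 2.0
  persistence_class: oral_reference
  hazard_ratio: 1.0
- name: teriparatide
  rr_hip: 0.25
  rr_vert: 0.35
  rr_nhnv: 0.47
  annual_drug_cost: 14514.0
  admin_events: []
  max_treatment_years: 2.0
  offset_years: 2.0
  persistence_class: injectable_hr_adjusted
  hazard_ratio: 0.5
tables:
  life_table: life_table.csv
  incidence: incidence.csv
  persistence: persistence.csv
  mortality_rr: mortality_rr.csv
  baseline_utility: baseline_utility.csv
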