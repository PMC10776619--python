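scenario_label: central
population_size: 274000.0
prevalence_carriers: 0.0067
clinical_eligibility_rate: 0.0098
positivity_among_eligible: 0.1
prevalence_in_not_eligible: 0.0058
surgery_mix:
  both: 0.2585
  rrso_only: 0.2915
  rrm_only: 0.2115
  none: 0.2385
cancer_risks:
  none:
    breast_only: 0.49
    ovarian_only: 0.09
    both_cancers: 0.215
    no_cancer: 0.205
  rrm_only:
    breast_only: 0.0441
    ovarian_only: 0.2856
    both_cancers: 0.0194
    no_cancer: 0.6509
  rrso_only:
    breast_only: 0.3413
    ovarian_only: 0.008
    both_cancers: 0.0042
    no_cancer: 0.6465
  both:
    breast_only: 0.0349
    ovarian_only: 0.0118
    both_cancers: 0.0004
    no_cancer: 0.9529
costs:
  gyn_visit_us: 51.65
  genetic_counselling_testing: 1099.48
  rrso: 1436.0
  rrm: 1960.0
  ovarian_cancer_surgery: 6791.0
  breast_cancer_mastectomy: 3524.45
  chemotherapy: 2226.0
  parp_inhibitor: 82344.0
  radiotherapy: 6000.0
  fu_brca_positive_per_year: 198.2
  fu_brca_negative_or_unknown_per_year: 69.6
timeline:
  age_consent: 18
  cancer_onset_age: 45
  fu_step1_years: 27
  fu_step2_years: 35
  exit_age: 80
  cycle_years: 62
  prophylactic_surgery_age: 40
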