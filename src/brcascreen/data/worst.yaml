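scenario_label: worst
population_size: 274000.0
prevalence_carriers: 0.0077
clinical_eligibility_rate: 0.0179
positivity_among_eligible: 0.1
prevalence_in_not_eligible: 0.0068
surgery_mix:
  both: 0.153
  rrso_only: 0.297
  rrm_only: 0.187
  none: 0.363
cancer_risks:
  none:
    breast_only: 0.4758
    ovarian_only: 0.0858
    both_cancers: 0.3042
    no_cancer: 0.1342
  rrm_only:
    breast_only: 0.1808
    ovarian_only: 0.2744
    both_cancers: 0.1156
    no_cancer: 0.4292
  rrso_only:
    breast_only: 0.4675
    ovarian_only: 0.0385
    both_cancers: 0.0395
    no_cancer: 0.4545
  both:
    breast_only: 0.1582
    ovarian_only: 0.0646
    both_cancers: 0.0134
    no_cancer: 0.7638
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
  cancer_onset_age: 35
  fu_step1_years: 17
  fu_step2_years: 45
  exit_age: 80
  cycle_years: 62
  prophylactic_surgery_age: 35
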