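scenario_label: best
population_size: 274000.0
prevalence_carriers: 0.0059
clinical_eligibility_rate: 0.0047
positivity_among_eligible: 0.1
prevalence_in_not_eligible: 0.0051
surgery_mix:
  both: 0.3584
  rrso_only: 0.2816
  rrm_only: 0.2016
  none: 0.1584
cancer_risks:
  none:
    breast_only: 0.4819036192761448
    ovarian_only: 0.08698260347930413
    both_cancers: 0.14807038592281546
    no_cancer: 0.28304339132173567
  rrm_only:
    breast_only: 0.0096
    ovarian_only: 0.232
    both_cancers: 0.003
    no_cancer: 0.7554
  rrso_only:
    breast_only: 0.2309
    ovarian_only: 0.0072
    both_cancers: 0.0022
    no_cancer: 0.7597
  both:
    breast_only: 0.0062
    ovarian_only: 0.0093
    both_cancers: 0.0001
    no_cancer: 0.9844
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
  cancer_onset_age: 60
  fu_step1_years: 42
  fu_step2_years: 20
  exit_age: 80
  cycle_years: 62
  prophylactic_surgery_age: 45
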