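# Model parameters, urban setting.  Uncertain scalars are [base, lo95, hi95].
# Compliance values and the background life table are synthetic assumptions,
# not published estimates; everything else is a transcribed published value.
setting: urban

prevalence:
  npdr: [0.149, 0.106, 0.204]
  pdr: [0.011, 0.005, 0.023]
  dme: [0.026, 0.023, 0.029]

transitions:
  normal_to_npdr: [0.0328, 0.0184, 0.0578]
  normal_to_pdr: [0.0024, 0.0009, 0.0063]
  npdr_to_pdr: [0.0106, 0.0040, 0.0278]
  npdr_to_dme: [0.0107, 0.0096, 0.0118]
  pdr_to_dme: [0.0290, 0.0261, 0.0319]
  pdr_to_svi: [0.0278, 0.0100, 0.0744]
  dme_to_svi: [0.0500, 0.0450, 0.0550]
  treated_pdr_to_svi: [0.0116, 0.0005, 0.0268]
  treated_dme_to_svi: [0.0300, 0.0270, 0.0330]

utilities:
  no_dr: [0.95, 0.92, 0.99]
  npdr: [0.79, 0.71, 0.87]
  pdr: [0.70, 0.63, 0.77]
  dme: [0.70, 0.63, 0.77]
  svi: [0.55, 0.50, 0.61]

tests:
  community:
    normal_called_npdr: [0.05, 0.04, 0.06]
    normal_called_normal: [0.95, 0.86, 1.00]
    npdr_called_normal: [0.22, 0.20, 0.24]
    pdr_called_npdr: [0.03, 0.02, 0.04]
    pdr_called_normal: [0.02, 0.01, 0.03]
    dme_sensitivity: [0.82, 0.74, 0.90]
    dme_specificity: [0.79, 0.71, 0.87]
  telemedicine:
    normal_called_npdr: [0.04, 0.03, 0.05]
    normal_called_normal: [0.96, 0.86, 1.00]
    npdr_called_normal: [0.42, 0.38, 0.46]
    pdr_called_npdr: [0.19, 0.17, 0.21]
    pdr_called_normal: [0.02, 0.01, 0.03]
    dme_sensitivity: [0.80, 0.72, 0.88]
    dme_specificity: [0.95, 0.86, 1.00]

costs:
  hospital_exam_total: 100.00
  photocoagulation: 137.60
  anti_vegf: 1741.46
  followup_maintain: 122.32
  svi_first_year: 8800.0
  svi_subsequent_year: 3600.0
  uncertainty_fraction:
    screening: 0.20
    hospital_exam_total: 0.20
    photocoagulation: 0.50
    anti_vegf: 0.50
    followup_maintain: 0.50
    svi_first_year: 0.50
    svi_subsequent_year: 0.50

mortality:
  rr_diabetes: 1.97
  rr_svi: 3.9
  svi_multiplier_mode: replace
  life_table:
    kind: gompertz
    a: 0.004
    b: 0.085
    age_min: 50
    age_max: 110

economics:
  discount_rate: 0.035
  n_cycles: 30
  cycle_length_years: 1
  start_age: 50
  persons_screened_per_year: 20000
  exchange_rate_cny_per_usd: 6.9762
  wtp_1x_usd_per_qaly: 12000

compliance:                       # synthetic assumptions (unpublished source)
  uptake: [0.80, 0.72, 0.88]
  referral_acceptance: [0.70, 0.63, 0.77]

options:
  treated_pdr_to_dme: false
  dme_false_positive_referrals: false
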