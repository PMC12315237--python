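# ADNI-like site preset: mildly impaired research cohort with long follow-up,
# heavy phenotype missingness and ~20% dementia at baseline.
n_participants: 500
visit_count_range: [2, 12]
interval_range_months: [6.0, 12.0]
missingness_rates:
  cognitive: 0.30
  mri: 0.39
  diagnosis: 0.30
baseline_age_mean: 73.0
baseline_age_sd: 7.2
onset_mean: 75.0
onset_sd: 6.0
apoe4_probs: [0.5, 0.4, 0.1]
apoe4_onset_shift_years: 2.5
cdr_jitter_years: 1.0
label_noise: 0.05
noise_scale: 1.0
# Empirical targets of the preset (used only by sanity checks):
baseline_mmse_target: 25.5
baseline_mmse_tolerance: 1.0
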