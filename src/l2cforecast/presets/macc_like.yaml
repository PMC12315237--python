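# MACC-like site preset: memory-clinic population — more advanced disease
# (earlier onset relative to age), shorter histories, MRI-heavy missingness
# but near-complete cognitive and diagnostic ascertainment.
n_participants: 500
visit_count_range: [2, 6]
interval_range_months: [9.0, 15.0]
missingness_rates:
  cognitive: 0.02
  mri: 0.53
  diagnosis: 0.01
baseline_age_mean: 72.7
baseline_age_sd: 7.9
onset_mean: 71.0
onset_sd: 6.0
apoe4_probs: [0.5, 0.4, 0.1]
apoe4_onset_shift_years: 2.5
cdr_jitter_years: 1.0
label_noise: 0.05
noise_scale: 1.0
baseline_mmse_target: 23.2
baseline_mmse_tolerance: 1.5
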