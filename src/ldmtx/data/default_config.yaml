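seed: 1
drug: methotrexate
renal_only: true
n_cases: 8000
renal_fraction: 0.3
duplicate_fraction: 0.05
min_reports: 3
prr_min: 2.0
chi2_min: 4.0
ror_ci_low_min: 1.0
ic025_min: 0.0
c0_umol_L: 0.16
m0_mg: 2.3
egfr_norm: 90.0
label_doses_mg:
- 7.5
- 10.0
- 15.0
- 20.0
tablet_mg: 2.5
rcs_noise_sd: 0.01
rcs_n_per_dose: 30
calib_noise_cv: 0.15
calib_doses_mg:
- 7.5
- 15.0
calib_n_subjects: 6
calib_n_starts: 2
assess_n: 50
pbpk_params_file: null
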