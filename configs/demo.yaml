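# Demo cohort: 25 healthy atlas subjects + 6 patients (two sessions each)
# on a U-bend aorta phantom at clinical 4D-flow resolution.
seed: 20260917
n_healthy: 25
n_patients: 6
template:
  geometry: u-bend
  radius_mm: 10.0
  length_mm: 80.0
  bend_radius_mm: 35.0
  spacing_mm: 2.5
  nt: 30
  dt_ms: 32.0
  vmax_peak: 1.0
  pwv_mps: 8.0
  noise_sd: 0.05
cohort_sd_vmax: 0.10
cohort_sd_radius: 0.05
patient_vmax_factor: 1.35
patient_session_sd: 0.03
patient_pwv_mean: 8.5
patient_pwv_sd: 1.5
mu: 0.0032
z_threshold: 1.96
angle_threshold_deg: 120.0
dt_target_ms: 20.0
section_spacing_mm: 10.0
register_followup: true
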