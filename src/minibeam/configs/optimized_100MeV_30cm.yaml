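experiment: scan
seed: 1
nozzle:
  preset: optimized
  air_gap_cm: 30.0
  focal_length_cm: 100.0
source:
  energy_MeV: 100.0
  energy_spread: 0.01
  sigma_x_mm: 6.5
  sigma_y_mm: 10.0
  div_x_mrad: 5.0
  div_y_mrad: 5.0
  r_xx: -1.0
  r_yy: -1.0
scan:
  step_T: 0.04
  n_particles: 100000
  refine_fraction: 0.01
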