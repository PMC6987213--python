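# Optimised nozzle, 100 MeV, 10 cm air gap; minimum-size source row
experiment: scan
seed: 1
nozzle:
  preset: optimized
  air_gap_cm: 10.0
  focal_length_cm: 100.0
source:
  energy_MeV: 100.0
  energy_spread: 0.01
  sigma_x_mm: 4.0
  sigma_y_mm: 4.0
  div_x_mrad: 3.0
  div_y_mrad: 3.0
  r_xx: -1.0
  r_yy: -1.0
scan:
  step_T: 0.04
  n_particles: 100000
  refine_fraction: 0.01
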