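# Six-prong diffuse excitation of a homogeneous phantom at 2 kHz.
# Run:  asyncoce report --config examples/scene_diffuse.yaml --seed 1 --out scratch/run
protocol:
  f_a_hz: 100082.0
  n_x: 1536
  n_flyback: 142
  n_b: 2
  n_y: 75
  range_x_m: 0.012
  range_y_m: 0.012
  f0_hz: 2000.0
sources:
  n_sources: 6
  circle_diameter_m: 0.020
  amplitude_m: 1.0e-07
medium:
  k_bg: 444.4      # cycles/m -> c = 4.5 m/s at 2 kHz
  rho_kg_m3: 1000.0
noise:
  snr_db: 20.0
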