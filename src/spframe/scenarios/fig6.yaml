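# Four SP localizers, 10 degree tilt: 4 vs 12 coordinate sets.
frame:
  kind: sp
  aspects: [anterior, left, right, posterior]
defaults: {z_start_mm: 27.0, z_stop_mm: 155.0, z_step_mm: 2.0, iterations: 2097152, noise_mm: 1.0}
scenarios:
  - {id: fig6_classic, mode: classic, theta_deg: 10.0}
  - {id: fig6_three_point, mode: three_point, theta_deg: 10.0}
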