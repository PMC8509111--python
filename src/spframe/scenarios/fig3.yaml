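# Three SP localizers, untilted slices: classic (3 sets) vs three-point (9 sets).
frame:
  kind: sp
  aspects: [anterior, left, right]
defaults: {z_start_mm: 5.0, z_stop_mm: 155.0, z_step_mm: 2.0, iterations: 2097152, noise_mm: 1.0}
scenarios:
  - {id: fig3_classic, mode: classic, theta_deg: 0.0}
  - {id: fig3_three_point, mode: three_point, theta_deg: 0.0}
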