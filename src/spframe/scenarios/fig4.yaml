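# Three SP localizers, 10 degree anteroposterior tilt: 3 vs 9 coordinate sets.
# The minimum height is larger than at 0 degrees so the tilted plane clears
# the frame base posteriorly.
frame:
  kind: sp
  aspects: [anterior, left, right]
defaults: {z_start_mm: 21.0, z_stop_mm: 155.0, z_step_mm: 2.0, iterations: 2097152, noise_mm: 1.0}
scenarios:
  - {id: fig4_classic, mode: classic, theta_deg: 10.0}
  - {id: fig4_three_point, mode: three_point, theta_deg: 10.0}
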