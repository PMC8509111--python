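# Four tilted SP localizers (12 sets) against four untilted N-localizers
# (4 xyz + 8 xy sets) -- the cross-device accuracy comparison.
defaults: {z_step_mm: 2.0, iterations: 2097152, noise_mm: 1.0}
scenarios:
  - id: fig7_sp
    mode: three_point
    theta_deg: 10.0
    z_start_mm: 27.0
    z_stop_mm: 155.0
    frame: {kind: sp, aspects: [anterior, left, right, posterior]}
  - id: fig7_n
    mode: n_localizer
    theta_deg: 0.0
    z_start_mm: 10.0
    z_stop_mm: 130.0
    frame: {kind: n, aspects: [anterior, left, right, posterior]}
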