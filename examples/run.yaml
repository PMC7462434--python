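# Standard two-impulse scenario on the discrete sheet at moderate coupling.
model:
  R: 0.4
grid:
  n_lateral: 50
  z_extent: 300.0
  t_end: 800.0
stimulus:
  pairs: [[30, 0.0], [20, 10.0]]
output:
  store_w: false
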