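# Temporal-dispersion variant: short cortex<->hippocampus delays, long
# heterogeneous relay delays (loop span 12-100 ms).
loop:
  h: 100
  c: 300
  dispersion: true
  forward_weight_mean: 1.35
training:
  cue: A
  target: B
  delta_t_ms: 120
  trials: 60
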