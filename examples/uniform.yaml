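# Adjusted reference network: uniform 50 ms loop delays.
loop:
  h: 100
  c: 300
  d: 50
training:
  cue: A
  target: B
  delta_t_ms: 120
  trials: 60
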