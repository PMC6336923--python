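state:
  A:
  - [0.98]
  B:
  - [0.0]
  Q:
  - [0.002229713739418092]
  x0: [0.0]
  P0:
  - [0.25]
  mask_A:
  - [false]
  mask_B:
  - [false]
  mask_Q:
  - [false]
  mask_x0: [false]
  mask_P0:
  - [false]
channels:
- name: rt
  kind: lognormal
  bias: -0.6394
  C: [1.0]
  D: []
  dispersion: 0.04
  censorable: true
  mask_bias: false
  mask_C: [false]
  mask_D: []
  mask_dispersion: false
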