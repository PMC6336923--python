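state:
  A:
  - [1.0]
  B:
  - [0.09]
  Q:
  - [0.004]
  x0: [0.0]
  P0:
  - [0.01]
  mask_A:
  - [false]
  mask_B:
  - [false]
  mask_Q:
  - [true]
  mask_x0: [false]
  mask_P0:
  - [false]
channels:
- name: accuracy
  kind: bernoulli
  bias: -2.0
  C: [1.0]
  D: []
  dispersion: null
  censorable: false
  mask_bias: true
  mask_C: [false]
  mask_D: []
  mask_dispersion: true
- name: rt
  kind: lognormal
  bias: -0.2231435513142097
  C: [-0.12]
  D: []
  dispersion: 0.04
  censorable: true
  mask_bias: true
  mask_C: [true]
  mask_D: []
  mask_dispersion: true
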