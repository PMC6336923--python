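state:
  A:
  - [0.999, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.999, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.999, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.999, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.999, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.999, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.999, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.999, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.999]
  B:
  - [0.14, 0.0, 0.0, 0.0]
  - [0.04666666666666667, 0.0, 0.0, 0.0]
  - [0.0, 0.14, 0.0, 0.0]
  - [0.0, 0.04666666666666667, 0.0, 0.0]
  - [0.0, 0.0, 0.03, 0.0]
  - [0.0, 0.0, 0.01, 0.0]
  - [0.0, 0.0, 0.0, 0.03]
  - [0.0, 0.0, 0.0, 0.01]
  - [0.02, 0.02, 0.02, 0.02]
  Q:
  - [0.0001, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0001, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0001, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0001, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0001, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0001, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0001, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0001, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0001]
  x0: [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  P0:
  - [0.001, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.001, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.001, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.001, 0.0, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.001, 0.0, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.001, 0.0, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.001, 0.0, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.001, 0.0]
  - [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.001]
  mask_A:
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  mask_B:
  - [false, false, false, false]
  - [false, false, false, false]
  - [false, false, false, false]
  - [false, false, false, false]
  - [false, false, false, false]
  - [false, false, false, false]
  - [false, false, false, false]
  - [false, false, false, false]
  - [false, false, false, false]
  mask_Q:
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  mask_x0: [false, false, false, false, false, false, false, false, false]
  mask_P0:
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
  - [false, false, false, false, false, false, false, false, false]
channels:
- name: acc_gain1
  kind: bernoulli
  bias: -0.4
  C: [1.0, 0.6, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.8]
  D: []
  dispersion: null
  censorable: false
  mask_bias: true
  mask_C: [false, false, false, false, false, false, false, false, false]
  mask_D: []
  mask_dispersion: true
- name: acc_gain2
  kind: bernoulli
  bias: -0.4
  C: [0.0, 0.0, 1.0, 0.6, 0.0, 0.0, 0.0, 0.0, 0.8]
  D: []
  dispersion: null
  censorable: false
  mask_bias: true
  mask_C: [false, false, false, false, false, false, false, false, false]
  mask_D: []
  mask_dispersion: true
- name: acc_loss1
  kind: bernoulli
  bias: -0.4
  C: [0.0, 0.0, 0.0, 0.0, 1.0, 0.6, 0.0, 0.0, 0.8]
  D: []
  dispersion: null
  censorable: false
  mask_bias: true
  mask_C: [false, false, false, false, false, false, false, false, false]
  mask_D: []
  mask_dispersion: true
- name: acc_loss2
  kind: bernoulli
  bias: -0.4
  C: [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.6, 0.8]
  D: []
  dispersion: null
  censorable: false
  mask_bias: true
  mask_C: [false, false, false, false, false, false, false, false, false]
  mask_D: []
  mask_dispersion: true
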