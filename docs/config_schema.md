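# Model configuration schema

A model config is a single YAML document with exactly two top-level
keys. Unknown fields anywhere are errors, not warnings. Example configs
live under `configs/`.

```yaml
state:
  A:  [[0.98]]          # d x d transition matrix
  B:  [[1.0]]           # d x p input loading (omit or [] for no inputs)
  Q:  [[0.0015]]        # d x d process-noise covariance (symmetric PSD)
  x0: [0.0]             # initial state mean (length d)
  P0: [[0.0001]]        # initial state covariance (symmetric PSD)
  mask_A:  [[false]]    # elementwise: true = free (estimated), false = fixed
  mask_B:  [[false]]    # defaults: A/B/Q free, x0/P0 fixed
  mask_Q:  [[false]]
  mask_x0: [false]
  mask_P0: [[false]]
channels:               # ordered list; at least one
  - name: rt            # column suffix in session CSVs (y.rt, status.rt, ...)
    kind: lognormal     # normal | lognormal | gamma | bernoulli | point_process
    bias: -0.6394       # scalar intercept of the linear predictor
    C: [1.0]            # state loadings (length d)
    D: []               # covariate loadings (length q; matches i.* columns)
    dispersion: 0.04    # sigma^2 (normal/lognormal) or shape nu (gamma);
                        # omit for bernoulli / point_process
    censorable: true    # continuous kinds only
    mask_bias: false    # free/fixed masks, defaults all-free
    mask_C: [false]
    mask_D: []
    mask_dispersion: false
```

Session data are CSV files with one row per trial (reported 1-based):
columns `y.<channel>`, `u.<j>`, `i.<j>` (0-based input/covariate
indices), `status.<channel>` with values `observed` / `missing` /
`censored`, and `threshold.<channel>` carrying the censoring threshold
where status is `censored` (empty elsewhere). Lines starting with `#`
are comments (simulators record their seed this way).
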