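# Methods

## Model

A session of K trials is modeled by a latent state `x[k]` (dimension d)
with linear-Gaussian dynamics `x[k+1] = A x[k] + B u[k] + w[k]`,
`w ~ N(0, Q)`, `x[1] ~ N(x0, P0)`, observed through one or more channels
that are conditionally independent given the state. Each channel maps
`eta = bias + C x[k] + D i[k]` through a fixed canonical link into its
family: logistic for Bernoulli and per-bin point-process indicators, log
link for the gamma mean and the log-normal location, identity for
normal. The gamma family is parameterized by (shape nu, mean e^eta), so
C is the effect on the log-mean — the natural scale for reaction times.
History dependence is expressed by letting the analyst place lagged
observations into the covariate columns `i[k]`; nothing is lagged
implicitly.

Every parameter (A, B, Q, x0, P0, bias, C, D, dispersion) carries an
elementwise boolean mask; fixed entries are never touched by any
estimator. Per-observation status flags distinguish observed, missing
at random, and censored-from-above entries; censored entries carry their
per-trial threshold (a constant threshold is broadcast at simulation
time), supporting threshold sweeps with one data model.

## State inference

The filter tracks a Gaussian belief. The predict step is exact. The
update step has three tiers:

1. **Conjugate fold.** Observed normal and log-normal entries are exact
   Gaussian evidence in state space and are folded in as sequential
   scalar Kalman updates (with the log-Jacobian for log-normal).
2. **Rank-one moment matching.** A single remaining non-Gaussian term
   (Bernoulli, gamma, or a censored survival term) touches the state
   only through its scalar predictor t = eta. The 1-D posterior
   `p(t) ∝ N(t; m, s²) exp(l(t))` is integrated by Gauss–Hermite
   quadrature centered on its Laplace approximation (mode by safeguarded
   damped Newton; 25 nodes for observed terms, 51 for the more skewed
   censored terms), giving the posterior mean, variance, and normalizer
   essentially exactly; the state moments follow through the rank-one
   gain. Against brute-force grids the error is below 1e-12 for
   Bernoulli/gamma/log-normal updates and ~1e-16 for censored
   log-normal (a 4001-point ±8-SD grid is itself the larger error
   source in deep-tail censoring).
3. **Joint Laplace.** Only when two or more non-Gaussian terms coincide
   on one trial does the update fall back to mode-plus-curvature
   Laplace by damped Newton in state space (step halving, ≤100
   iterations, gradient tolerance 1e-9, initialized at the predicted
   mean).

For purely normal channels the recursion reduces exactly to the Kalman
filter, and the per-trial log-likelihood contributions are the exact
innovations form; otherwise they are the corresponding approximate
marginals (exact quadrature in tier 2, Laplace in tier 3) and are
documented as approximate. Missing entries contribute nothing: a trial
with all channels missing leaves the belief and the log-likelihood
untouched, exactly.

Fixed-interval smoothing is the RTS backward recursion on the per-trial
Gaussians; lag-one smoothed covariances use the smoother-gain identity
`Cov(x[k], x[k-1] | Y) = P[k|K] J[k-1]'`, which is exact for Gaussian
beliefs and is verified against a joint-multivariate-normal oracle.
Covariances are symmetrized after every step; a singular inverse gets
one 1e-10 jitter retry and then fails loudly with the trial index.
`OnlineFilter` runs the same recursion one trial at a time (streaming a
session reproduces the batch filter bit for bit) and allows the model
to be swapped mid-stream after a re-fit.

## Censoring treatments

- `mar` drops censored entries (a deliberately naive baseline — the
  missingness is informative, so this biases the state away from the
  slow tail).
- `imputation` replaces each censored entry with an inverse-CDF draw
  from the channel's predictive distribution at the one-step *predicted*
  state, truncated to (threshold, ∞). The predicted (not filtered or
  smoothed) state preserves causal filtering semantics. One draw per
  datum by default (multiple draws are averaged on the log scale for
  positive families); every draw is logged for audit and reused by the
  M-step. A truncated mass below 1e-12 is an error.
- `full_likelihood` adds the analytic survival term
  `log S(threshold | eta)` — Gaussian survival for normal/log-normal,
  upper regularized incomplete gamma for gamma — with analytic
  Mills-ratio first and second derivatives, to the update objective and
  the M-step.

All three treatments are bit-identical on sessions with no censored
flags. Self-consistency between E- and M-steps: mar excludes censored
trials from channel updates, imputation uses the logged draws, and
full_likelihood carries the expected survival term.

## Parameter estimation

**EM.** The E-step runs filter+smoother and assembles E[x], E[x x'],
and the lag-one cross moments. The M-step solves masked least-squares
normal equations for (A, B) rows, sets free Q entries from the expected
residual outer product, and updates x0/P0 from the first smoothed
moment. Channel coefficients solve a closed-form weighted least squares
for normal/log-normal (the state-uncertainty term C P C' enters the
normal equations); Bernoulli, gamma, and censored channels use damped
Newton on the expected log-likelihood, with the expectation over eta
taken by 21-node Gauss–Hermite quadrature. The quadrature spread is
held fixed within each inner Newton solve and refreshed by an outer
fixed-point loop so the objective and its derivatives stay mutually
consistent. Dispersions: closed-form expected residual variance
(normal/log-normal), trigamma Newton for the gamma shape, and a bounded
1-D search on the log scale when censored survival terms are active.
Separation in a Bernoulli channel (near-singular Hessian) gets a 1e-4
ridge and a warning. Stopping: `max_iters` (default 250) or relative
log-likelihood change below `tol` (default 1e-6; `tol=0` gives pure
iteration-count stopping). With only normal channels the log-likelihood
trace is non-decreasing (checked to 1e-8); with non-Gaussian channels
small fluctuations of the approximate marginal are possible and larger
decreases trigger a warning rather than an error.

**Direct ML (`fit_ml`).** By Fisher's identity the score of the
marginal likelihood is the posterior expectation of the complete-data
score, so one E-step yields both the log-likelihood and its exact
gradient for the same Gaussian approximation (the loading gradients
include the Stein covariance term `P C E[l'']`). L-BFGS-B on this pair,
with variance-like parameters on the log scale, reaches the EM fixed
point in roughly 30 gradient steps where plain EM needs hundreds of
sweeps along weakly identified ridges (most prominently the state-scale
direction Q·C²). The score matches finite differences to ~1e-4 on
moment-matched models; on the joint-Laplace path a small systematic gap
between the approximate marginal and the expected score remains, which
is why the optimizer's target (the score's zero) is the EM fixed point
itself.

**Identifiability.** The model is invariant to jointly rescaling the
state, Q, and all loadings, so when both Q and every loading are free,
one designated loading is pinned at 1 (`anchor="auto"`, on by default;
overridable). Anchoring through a strongly informative channel (e.g.,
the RT loading rather than a binary channel's) makes the remaining
parameters much better conditioned. Deviance differences between nested
models are invariant to the anchoring convention (tested by explicit
rescaling).

**Initialization.** `initialize_params` provides deterministic
weakly-informative starts: A = 0.99 I, B = 0, Q = 1e-3 I, x0 = 0,
P0 = I, channel coefficients from a small IRLS GLM on covariates alone,
state loadings 0.01. Caveat: on models with a shallow Q·C² ridge a
near-zero loading start can converge to a rescaled solution (small Q,
large C, product conserved); for recovery studies we recommend (and the
tests use) neutral mid-range starts for loadings instead.

## Goodness of fit

`deviance` is −2 × the (approximate) marginal log-likelihood from the
forward filter; AIC/BIC use the free-parameter census from the masks.
`param_covariance` inverts the observed information computed by central
finite differences over the free-parameter vector (relative step 1e-4
with an absolute floor), projects to the nearest PSD matrix if needed
(flagged), and reports standard errors and 95% Wald intervals.
Finite differences were chosen over EM-internal curvature so the same
code path serves every family and censoring method.

## Simulators

`simulate` draws sessions by ancestral sampling from any valid model;
all randomness flows through one `numpy.random.default_rng(seed)` in a
fixed consumption order (state noise first, then channels in declaration
order), so regeneration is bit-identical. Censorable channels compare
each raw draw to its trial threshold; the raw draw is retained for
scoring and withheld from the session.

Three experiment builders emulate common study designs:

- **Learning sessions** (`make_learning_experiment`): 61 trials, a 1-D
  learning state with constant drive (A=1, B=0.09, Q=0.004), a binary
  accuracy channel (bias −2, loading 1: accuracy rises from ~0.12 to
  ~0.95 across the session, inflecting after ~trial 20) and a log-normal
  RT channel shortening with learning; by default 22 of 61 trials are
  non-response trials flagged missing on both channels (a configurable
  fraction).
- **Censored-RT sessions** (`make_censored_rt_experiment`): 200 trials,
  a 1-D inattention state mean-reverting (AR 0.98, q=0.0015) about a
  frozen piecewise-linear profile with peaks near trials 40 and 90 and
  its maximum at the final trial; log-normal RT (sigma²=0.04, loading 1,
  bias −0.6394 s.t. the default 1.3 s threshold censors 49/200 trials
  in expectation). The companion `censored_rt_estimation_spec` is the
  analyst's model: the drift profile is treated as unknown and absorbed
  into the random-walk noise (Q inflated by the mean squared drift
  step); `known_variance=True` pins both noise variances.
- **Gain/loss learning** (`make_gain_loss_experiment`): 160 trials over
  four interleaved contingencies (40 each, seed-fixed order), a 9-D
  state (two actor-critic-like states per contingency plus one global
  state), and four Bernoulli accuracy channels of which only the active
  contingency's is observed on each trial (the observation parameters
  are trial-invariant, so per-trial channel selection is expressed by
  missingness). Gain blocks learn faster than loss blocks (rates
  0.14 vs 0.03), producing the gain-over-loss accuracy asymmetry.
  Shipped as an illustrative fixture.

What these simulators do and do not capture: they generate data exactly
from the model class the estimators assume (up to the deliberately
misspecified drift in the censored-RT analyst model), so passing tests
demonstrate correct inference and estimation under the stated
conditions — not robustness to the sequential dependencies, lapses,
non-stationarities, or model misspecification of real behavioral data.

## Problem sizes and numerical choices

The test and benchmark problem sizes are chosen as representative desk
scale: censored-RT comparisons use 200-trial sessions (RMSE and
censored-count summaries averaged over 20 replicates in the tests and
200 in the benchmark script); parameter recovery uses 2000-trial
sessions and 20 replicates; the censoring-robustness study fits noise
variances at censoring fractions 5–50% (thresholds 1.882/1.488/1.218/
0.993 s computed from the fixture's survival curve) with 20 replicates
per level. Key tolerances: Newton gradient 1e-9 (filter), 1e-8
(M-step); covariance jitter 1e-10 (once); truncation-mass floor 1e-12;
survival probabilities floored at 1e-300 before logs. Ties and
degenerate inputs: empty sessions yield empty trajectories and zero
deviance; K=1 sessions skip transition updates; all-fixed models are
legal everywhere (estimation is a no-op and the covariance report is
empty).

## Known limitations

- With several non-Gaussian channels on the same trial the update is
  joint Laplace, not moment matching; its accuracy degrades for very
  skewed or weakly informed posteriors.
- The marginal likelihood for non-Gaussian data is approximate, so EM
  monitoring, deviance, and information-criteria comparisons inherit
  that approximation.
- Censoring is from above only; censoring from below or two-sided
  censoring is not supported.
- Beta and multinomial channels, continuous-time point processes, and
  marked point processes are out of scope.
- MAR-vs-full-likelihood contrasts depend on how deeply the state
  excursions exceed the censoring threshold; the censored-RT fixture's
  contrast is calibrated to its own frozen profile, not to any external
  dataset.
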