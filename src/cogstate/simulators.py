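"""Seeded generative simulators.

``simulate`` draws a session from any valid model by ancestral sampling.
Three canned experiment builders emulate common study designs:

* ``make_learning_experiment`` — a 61-trial associative-learning session
  with a rising 1-D learning state read out jointly through a binary
  accuracy channel and a log-normal reaction-time channel, with a
  configurable fraction of non-response trials marked missing.
* ``make_censored_rt_experiment`` — a 200-trial sustained-attention
  session in which a 1-D inattention state drifts through a
  rise-fall-rise-fall-rise profile (peaks near trials 40 and 90, maximum
  at the final trial) and log-normal reaction times are censored from
  above at a response-window threshold (default 1.3 s).
* ``make_gain_loss_experiment`` — a 160-trial probabilistic gain/loss
  learning session with four interleaved stimulus contingencies and a
  9-D state (two actor-critic states per contingency plus one global
  Q-learning-like state), shipped as an illustrative fixture.

All randomness flows through one ``numpy.random.default_rng(seed)``
stream consumed in a fixed order (state noise first, then channels in
declaration order), so regeneration with the same (spec, K, seed) is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _families as fam
from .model import (CENSORED, MISSING, OBSERVED, ModelSpec, ObservationChannel,
                    StateModel, TrialSession, validate_spec)

__all__ = ["SimulationOutput", "simulate", "make_learning_experiment",
           "make_censored_rt_experiment", "censored_rt_estimation_spec",
           "make_gain_loss_experiment"]


@dataclass
class SimulationOutput:
    """A simulated session bundled with its generating ground truth."""

    session: TrialSession
    latent: np.ndarray        # (K, d) true state trajectory
    raw_Y: np.ndarray         # (K, m) draws before censoring/missingness
    spec: ModelSpec
    seed: int


def _psd_sqrt(M):
    """Deterministic matrix square root of a PSD matrix (eigh-based)."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if not M.any():
        return np.zeros_like(M)
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    w = np.clip(w, 0.0, None)
    return V @ np.diag(np.sqrt(w)) @ V.T


def simulate(spec: ModelSpec, K: int, seed: int, U=None, I=None,
             thresholds=None, missing=None) -> SimulationOutput:
    """Ancestral sampling of a K-trial session from a model.

    ``thresholds`` (scalar or (K, m) array) activates censoring-from-above
    on censorable channels: a draw exceeding its trial threshold is flagged
    censored, the raw draw is withheld from the session (kept in
    ``raw_Y``), and the threshold is recorded.  ``missing`` is an optional
    boolean (K, m) mask flagging entries missing at random.
    """
    problems = validate_spec(spec)
    if problems:
        raise ValueError("invalid spec: " + "; ".join(problems))
    st = spec.state
    d, m, p = st.d, spec.m, st.p
    rng = np.random.default_rng(seed)

    U = np.zeros((K, p)) if U is None else np.asarray(U, dtype=float).reshape(K, p)
    q_cov = max((c.D.shape[0] for c in spec.channels), default=0)
    if I is None:
        I = np.zeros((K, q_cov))
    else:
        I = np.asarray(I, dtype=float)
        I = I.reshape(K, -1) if I.size else I.reshape(K, 0)

    thr = np.full((K, m), np.nan)
    if thresholds is not None:
        thr_in = np.asarray(thresholds, dtype=float)
        for j, c in enumerate(spec.channels):
            if c.censorable:
                thr[:, j] = thr_in if thr_in.ndim == 0 else thr_in.reshape(K, m)[:, j]

    # latent trajectory first: one fixed block of the RNG stream
    latent = np.zeros((K, d))
    if K:
        L0 = _psd_sqrt(st.P0)
        Lq = _psd_sqrt(st.Q)
        latent[0] = st.x0 + L0 @ rng.standard_normal(d)
        for k in range(1, K):
            latent[k] = (st.A @ latent[k - 1] + st.B @ U[k - 1]
                         + Lq @ rng.standard_normal(d))

    raw = np.zeros((K, m))
    status = np.full((K, m), OBSERVED, dtype=int)
    for j, c in enumerate(spec.channels):
        eta = c.bias + latent @ c.C + (I[:, :c.D.shape[0]] @ c.D if c.D.size else 0.0)
        raw[:, j] = fam.sample(c.kind, eta, c.dispersion, rng)

    Y = raw.copy()
    for j in range(m):
        over = np.isfinite(thr[:, j]) & (raw[:, j] > thr[:, j])
        status[over, j] = CENSORED
        Y[over, j] = np.nan
    # record thresholds only where they actually censored a draw
    thr_out = np.where(status == CENSORED, thr, np.nan)
    if missing is not None:
        miss = np.asarray(missing, dtype=bool).reshape(K, m)
        status[miss] = MISSING
        Y[miss] = np.nan
        thr_out[miss] = np.nan

    session = TrialSession(Y=Y, U=U, I=I, status=status, thresholds=thr_out)
    return SimulationOutput(session=session, latent=latent, raw_Y=raw,
                            spec=spec, seed=seed)


# ---------------------------------------------------------------------------
# fixture 1: associative learning (binary accuracy + log-normal RT)

def learning_model_spec() -> ModelSpec:
    """1-D learning-state model with joint accuracy and RT readout.

    The state rises under a constant drive; accuracy is logistic in the
    state (starting well below chance-corrected mastery, ending above
    90%), and median RT shortens as the task is learned.
    """
    state = StateModel(A=[[1.0]], B=[[0.09]], Q=[[0.004]], x0=[0.0], P0=[[0.01]],
                       mask_A=[[False]], mask_B=[[False]], mask_Q=[[True]],
                       mask_x0=[[False]], mask_P0=[[False]])
    accuracy = ObservationChannel(
        name="accuracy", kind="bernoulli", bias=-2.0, C=[1.0],
        mask_C=[False])   # loading anchored: the state is in accuracy-logit units
    rt = ObservationChannel(
        name="rt", kind="lognormal", bias=float(np.log(0.8)), C=[-0.12],
        dispersion=0.04, censorable=True)
    return ModelSpec(state=state, channels=[accuracy, rt])


def make_learning_experiment(seed: int, K: int = 61,
                             missing_fraction: float = 22 / 61) -> SimulationOutput:
    """Simulate one associative-learning session.

    Defaults give 61 trials of which about 36% are non-response trials,
    flagged missing on both the choice and the RT channel.
    """
    spec = learning_model_spec()
    U = np.ones((K, 1))
    sim = simulate(spec, K, seed, U=U)
    if missing_fraction > 0 and K > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
        n_miss = int(round(missing_fraction * K))
        miss_trials = rng.choice(K, size=n_miss, replace=False)
        miss = np.zeros((K, spec.m), dtype=bool)
        miss[miss_trials, :] = True   # non-response: both channels unobserved
        sim.session.status[miss] = MISSING
        sim.session.Y[miss] = np.nan
    return sim


# ---------------------------------------------------------------------------
# fixture 3: censored reaction times under an inattention state

# piecewise-linear drift profile of the inattention state: rises to a first
# peak near trial 40, dips, peaks again near trial 90, dips, then grows to
# its maximum at the final trial.  Values are frozen fixture constants;
# the RT bias is calibrated so the 1.3 s threshold censors ~49 of 200
# trials in expectation at this profile and noise level.
_RT_PROFILE_KNOTS = ((1, 0.00), (40, 1.00), (65, 0.35), (90, 0.88),
                     (130, 0.25), (200, 1.25))
_RT_AR = 0.98                    # mean-reversion of the state about the profile
_RT_STATE_NOISE = 0.0015         # per-trial process-noise variance
_RT_OBS_LOGVAR = 0.04            # log-RT observation variance sigma^2
_RT_BIAS = -0.6394               # log median RT at state 0 (about 0.53 s)
_RT_LOADING = 1.0                # log-RT increase per unit inattention


def _rt_profile(K: int) -> np.ndarray:
    ks = np.array([k for k, _ in _RT_PROFILE_KNOTS], dtype=float)
    vs = np.array([v for _, v in _RT_PROFILE_KNOTS], dtype=float)
    ks = ks * (K / 200.0)  # rescale knots for non-default session lengths
    return np.interp(np.arange(1, K + 1, dtype=float), ks, vs)


def make_censored_rt_experiment(seed: int, K: int = 200,
                                threshold: float = 1.3) -> SimulationOutput:
    """Simulate one censored-RT sustained-attention session.

    A 1-D inattention state follows the frozen two-peak drift profile plus
    Gaussian process noise; reaction times are log-normal with log-median
    increasing in the state and are censored from above at ``threshold``
    seconds (default 1.3 s, censoring roughly a quarter of trials at the
    default calibration).
    """
    profile = _rt_profile(K)
    drift = np.zeros((K, 1))
    if K > 1:
        # u_k steers the AR(1) state along the profile: m[k+1] = a m[k] + u[k]
        drift[:-1, 0] = profile[1:] - _RT_AR * profile[:-1]
    state = StateModel(A=[[_RT_AR]], B=[[1.0]], Q=[[_RT_STATE_NOISE]],
                       x0=[profile[0] if K else 0.0], P0=[[1e-4]],
                       mask_A=[[False]], mask_B=[[False]], mask_Q=[[False]],
                       mask_x0=[[False]], mask_P0=[[False]])
    rt = ObservationChannel(name="rt", kind="lognormal", bias=_RT_BIAS,
                            C=[_RT_LOADING], dispersion=_RT_OBS_LOGVAR,
                            censorable=True, mask_C=[False], mask_bias=False)
    spec = ModelSpec(state=state, channels=[rt])
    return simulate(spec, K, seed, U=drift,
                    thresholds=threshold if np.isfinite(threshold) else None)


def censored_rt_estimation_spec(known_variance: bool = True, K: int = 200) -> ModelSpec:
    """Analyst's model for the censored-RT experiment.

    The analyst does not know the deterministic drift profile, so the
    state is modeled as a random walk whose process-noise variance absorbs
    the drift increments (noise variance plus the mean squared drift step).
    With ``known_variance`` both noise variances are pinned at those
    values, mirroring a known-variance estimation setting; otherwise they
    are left free for EM.
    """
    profile = _rt_profile(K)
    if K > 1:
        drift = profile[1:] - _RT_AR * profile[:-1]
        drift_var = float(np.mean(drift ** 2))
    else:
        drift_var = 0.0
    q_eff = _RT_STATE_NOISE + drift_var
    state = StateModel(A=[[_RT_AR]], B=np.zeros((1, 1)), Q=[[q_eff]],
                       x0=[0.0], P0=[[0.25]],
                       mask_A=[[False]], mask_B=[[False]],
                       mask_Q=[[not known_variance]],
                       mask_x0=[[False]], mask_P0=[[False]])
    rt = ObservationChannel(name="rt", kind="lognormal", bias=_RT_BIAS,
                            C=[_RT_LOADING], dispersion=_RT_OBS_LOGVAR,
                            censorable=True, mask_C=[False], mask_bias=False,
                            mask_dispersion=not known_variance)
    return ModelSpec(state=state, channels=[rt])


# ---------------------------------------------------------------------------
# fixture 2: gain/loss probabilistic learning (illustrative)

def gain_loss_model_spec(gain_rate: float = 0.14, loss_rate: float = 0.03) -> ModelSpec:
    """9-D hybrid learning model: two states per contingency plus one global.

    Contingencies 0-1 are gain blocks, 2-3 loss blocks.  Each contingency
    has two actor-critic-like states driven by that contingency's trials;
    one global Q-learning-like state is driven by every trial.  Each
    contingency's accuracy channel reads a weighted combination of its own
    two states and the global state; off-contingency channels are missing
    on a given trial.
    """
    d = 9
    A = np.eye(d) * 0.999
    B = np.zeros((d, 4))
    for c in range(4):
        rate = gain_rate if c < 2 else loss_rate
        B[2 * c, c] = rate          # fast actor-critic component
        B[2 * c + 1, c] = rate / 3  # slow actor-critic component
    B[8, :] = 0.02                  # global state learns from all trials
    Q = np.eye(d) * 1e-4
    state = StateModel(A=A, B=B, Q=Q, x0=np.zeros(d), P0=np.eye(d) * 1e-3,
                       mask_A=np.zeros((d, d), bool), mask_B=np.zeros((d, 4), bool),
                       mask_Q=np.zeros((d, d), bool))
    channels = []
    for c in range(4):
        C = np.zeros(d)
        C[2 * c] = 1.0
        C[2 * c + 1] = 0.6
        C[8] = 0.8
        kind_label = "gain" if c < 2 else "loss"
        channels.append(ObservationChannel(
            name=f"acc_{kind_label}{c % 2 + 1}", kind="bernoulli", bias=-0.4,
            C=C, mask_C=np.zeros(d, bool)))
    return ModelSpec(state=state, channels=channels)


def make_gain_loss_experiment(seed: int, gain_rate: float = 0.14,
                              loss_rate: float = 0.03) -> SimulationOutput:
    """Simulate one 160-trial gain/loss session, 40 trials per contingency.

    Trials of the four contingencies are presented in a seed-fixed random
    order; each trial observes only the active contingency's accuracy
    channel (the other three are flagged missing).
    """
    spec = gain_loss_model_spec(gain_rate, loss_rate)
    K = 160
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))
    order = rng.permutation(np.repeat(np.arange(4), 40))
    U = np.zeros((K, 4))
    U[np.arange(K), order] = 1.0
    sim = simulate(spec, K, seed, U=U)
    miss = np.ones((K, 4), dtype=bool)
    miss[np.arange(K), order] = False
    sim.session.status[miss] = MISSING
    sim.session.Y[miss] = np.nan
    return sim
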