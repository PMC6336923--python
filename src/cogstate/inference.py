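"""Approximate Bayesian state inference for mixed-distribution observations.

The latent trajectory is tracked with a Gaussian approximation: each
trial's predict step is the exact linear-Gaussian propagation, and the
update step conditions on the trial's observations in three tiers.
Observed normal and log-normal channels are conjugate and fold in as
exact scalar Kalman updates.  A single remaining non-Gaussian term
(Bernoulli, gamma, or a censored survival term) acts on the state only
through its scalar linear predictor, so the posterior moments are
computed essentially exactly: a safeguarded damped Newton search finds
the mode of the predictor's 1-D posterior and mode-centered
Gauss-Hermite quadrature supplies its mean, variance, and normalizer,
which map back to state space through the rank-one gain.  Only when two
or more non-Gaussian terms coincide on one trial does the update fall
back to a joint Laplace (mode plus curvature) approximation found by
damped Newton in state space.  For purely normal channels the recursion
therefore reduces exactly to the Kalman filter.  Fixed-interval smoothing is the
Rauch-Tung-Striebel backward recursion applied to the per-trial Gaussian
approximations; lag-one smoothed covariances come from the smoother-gain
identity Cov(x_k, x_{k-1} | Y) = P_{k|K} J_{k-1}^T.

Per-trial log-likelihood contributions are the Laplace-approximate log
marginals of the observed data; they are exact in the all-Gaussian case
and approximate otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _families as fam
from .censoring import CensoringMethod, censored_eta_terms
from .model import (CENSORED, MISSING, OBSERVED, ModelSpec, StateModel,
                    TrialSession)

__all__ = ["PosteriorTrajectory", "predict_step", "update_step",
           "filter_pass", "smoother_pass", "OnlineFilter", "online_filter",
           "NewtonError", "trajectory_frame"]

_JITTER = 1e-10
NEWTON_MAX_ITER = 100
NEWTON_GRAD_TOL = 1e-9


class NewtonError(RuntimeError):
    """Mode search failed to converge; carries trial index and last iterate."""

    def __init__(self, msg, trial=None, last_iterate=None):
        super().__init__(msg)
        self.trial = trial
        self.last_iterate = last_iterate


@dataclass
class PosteriorTrajectory:
    """Per-trial predicted / filtered / smoothed Gaussian moments."""

    x_pred: np.ndarray        # (K, d) one-step predicted means
    P_pred: np.ndarray        # (K, d, d)
    x_filt: np.ndarray
    P_filt: np.ndarray
    loglik_trials: np.ndarray  # (K,) per-trial marginal contributions
    x_smooth: np.ndarray = None
    P_smooth: np.ndarray = None
    P_lag: np.ndarray = None   # (K, d, d); P_lag[k] = Cov(x_k, x_{k-1} | Y)

    @property
    def K(self) -> int:
        return self.x_pred.shape[0]

    @property
    def loglik(self) -> float:
        return float(self.loglik_trials.sum())


def _sym(M):
    return 0.5 * (M + M.T)


def _safe_inv(M, context=""):
    """Inverse with a single jitter retry on singular input."""
    try:
        return np.linalg.inv(M)
    except np.linalg.LinAlgError:
        try:
            return np.linalg.inv(M + _JITTER * np.eye(M.shape[0]))
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                f"singular covariance{' in ' + context if context else ''}; "
                f"jitter {_JITTER:g} did not help") from e


def predict_step(mean, cov, u_row, state: StateModel):
    """Propagate the Gaussian belief one trial ahead through the dynamics."""
    mean = np.asarray(mean, dtype=float).reshape(state.d)
    cov = np.asarray(cov, dtype=float).reshape(state.d, state.d)
    u_row = np.asarray(u_row, dtype=float).reshape(state.p)
    pred_mean = state.A @ mean + state.B @ u_row
    pred_cov = _sym(state.A @ cov @ state.A.T + state.Q)
    return pred_mean, pred_cov


def _trial_terms(y_row, status_row, thresholds_row, channels, i_row, method):
    """Collect per-channel (C, loglik-as-function-of-eta) contributions.

    Returns a list of (C_row, offset, kind, payload) where the
    log-likelihood of the entry at state x is evaluated at
    eta = offset + C_row @ x.  ``payload`` is ("obs", y, disp) for an
    observed (or imputed) value and ("cens", threshold, disp) for a
    full-likelihood censored term.
    """
    terms = []
    for j, ch in enumerate(channels):
        s = status_row[j]
        if s == MISSING:
            continue
        offset = ch.bias + (ch.D @ i_row if ch.D.size else 0.0)
        if s == OBSERVED:
            terms.append((ch.C, float(offset), ch.kind, ("obs", y_row[j], ch.dispersion)))
        elif s == CENSORED:
            thr = thresholds_row[j]
            if method.tag == "mar":
                continue
            if method.tag == "imputation":
                # draw is taken where update_step prepared it (y_row entry)
                terms.append((ch.C, float(offset), ch.kind, ("obs", y_row[j], ch.dispersion)))
            else:
                terms.append((ch.C, float(offset), ch.kind, ("cens", float(thr), ch.dispersion)))
    return terms


def _term_loglik(kind, payload, eta):
    """(loglik, d/deta, d2/deta2) of one term; eta scalar or array."""
    tag, a, disp = payload
    if tag == "obs":
        ll = fam.loglik(kind, a, eta, disp)
        d1, d2 = fam.dloglik(kind, a, eta, disp)
        return ll, d1, d2
    return censored_eta_terms(kind, a, eta, disp)


_GH_T, _GH_W = np.polynomial.hermite.hermgauss(25)
_LOG_GH_W = np.log(_GH_W)
# censored survival posteriors are more skewed: use a denser rule there
_GH_T_C, _GH_W_C = np.polynomial.hermite.hermgauss(51)
_LOG_GH_W_C = np.log(_GH_W_C)


def _scalar_term(kind, payload):
    """Fast scalar (loglik, d1, d2)(eta) closure for the 1-D mode search."""
    tag, a, disp = payload
    if tag == "cens":
        from scipy.special import gammaincc, gammaln, log_ndtr
        if kind in ("normal", "lognormal"):
            t0 = math.log(a) if kind == "lognormal" else a
            sd = math.sqrt(disp)

            def f(eta):
                z = (eta - t0) / sd
                ls = log_ndtr(z)
                r = math.exp(-0.5 * z * z - 0.9189385332046727 - ls)
                return ls, r / sd, (-z * r - r * r) / disp
        else:  # gamma
            nu = disp
            lg = gammaln(nu)

            def f(eta):
                s = nu * a * math.exp(-eta)
                ls = math.log(max(gammaincc(nu, s), 1e-300))
                d1 = math.exp(nu * math.log(s) - s - lg - ls) if s > 0 else 0.0
                return ls, d1, d1 * (s - nu - d1)
        return f
    if kind in ("bernoulli", "point_process"):
        y = a

        def f(eta):
            if eta >= 0:
                p = 1.0 / (1.0 + math.exp(-eta))
                ll = y * eta - eta - math.log1p(math.exp(-eta))
            else:
                e = math.exp(eta)
                p = e / (1.0 + e)
                ll = y * eta - math.log1p(e)
            return ll, y - p, -p * (1.0 - p)
    elif kind in ("normal", "lognormal"):
        z = math.log(a) if kind == "lognormal" else a
        extra = -z if kind == "lognormal" else 0.0
        c0 = -0.5 * (fam.LOG2PI + math.log(disp)) + extra

        def f(eta):
            r = z - eta
            return c0 - r * r / (2.0 * disp), r / disp, -1.0 / disp
    else:  # gamma observed
        nu = disp
        y = a
        from scipy.special import gammaln
        c0 = nu * math.log(nu) + (nu - 1.0) * math.log(y) - gammaln(nu)

        def f(eta):
            w = nu * y * math.exp(-eta)
            return c0 - nu * eta - w, w - nu, -w
    return f


def _moment_match_1d(m_t, s2, kind, payload, trial_index=None):
    """Moments and log normalizer of p(t) ∝ N(t; m_t, s2) exp(l(t)).

    Finds the mode of the log integrand by safeguarded damped Newton,
    then integrates with mode-centered Gauss-Hermite quadrature.  Exact
    up to quadrature error for any single scalar-predictor term.
    """
    term = _scalar_term(kind, payload)

    def g(t):
        ll, d1, d2 = term(t)
        return (ll - 0.5 * (t - m_t) ** 2 / s2,
                d1 - (t - m_t) / s2,
                d2 - 1.0 / s2)

    t_hat = m_t
    f, d1, d2 = g(t_hat)
    for _ in range(NEWTON_MAX_ITER):
        if abs(d1) < NEWTON_GRAD_TOL:
            break
        curv = d2 if d2 < -1e-12 else -1.0 / s2  # safeguard non-concave spots
        step = -d1 / curv
        tau = 1.0
        for _ in range(40):
            t_new = t_hat + tau * step
            f_new, d1_new, d2_new = g(t_new)
            if f_new >= f - 1e-12:
                break
            tau *= 0.5
        else:
            raise NewtonError("step halving exhausted in scalar update",
                              trial=trial_index, last_iterate=t_hat)
        t_hat, f, d1, d2 = t_new, f_new, d1_new, d2_new
    else:
        raise NewtonError(
            f"scalar mode search did not converge in {NEWTON_MAX_ITER} iterations"
            + (f" (trial {trial_index + 1})" if trial_index is not None else ""),
            trial=trial_index, last_iterate=t_hat)
    v_hat = -1.0 / d2 if d2 < -1e-12 else s2
    # Gauss-Hermite nodes centered on the Laplace approximation of p(t)
    gh_t, log_gh_w = (_GH_T_C, _LOG_GH_W_C) if payload[0] == "cens" \
        else (_GH_T, _LOG_GH_W)
    nodes = t_hat + math.sqrt(2.0 * v_hat) * gh_t
    g_vals = _term_loglik(kind, payload, nodes)[0] \
        - 0.5 * (nodes - m_t) ** 2 / s2
    log_f = log_gh_w + gh_t ** 2 + g_vals
    log_f_max = log_f.max()
    w = np.exp(log_f - log_f_max)
    z = w.sum()
    p = w / z
    mean_t = float(p @ nodes)
    var_t = float(p @ (nodes - mean_t) ** 2)
    log_norm = (0.5 * math.log(2.0 * v_hat) + log_f_max + math.log(z)
                - 0.5 * math.log(2.0 * math.pi * s2))
    return mean_t, var_t, log_norm


def update_step(pred_mean, pred_cov, y_row, status_row, thresholds_row,
                channels, i_row=(), method: CensoringMethod | None = None,
                trial_index: int | None = None):
    """Condition the predicted Gaussian on one trial's observations.

    Finds the mode of  log N(x; pred_mean, pred_cov) + sum of channel
    log-likelihood terms  by damped Newton (step halving), and returns the
    Gaussian (mode, curvature) approximation together with the
    Laplace-approximate log marginal of the trial's observed data.
    Channels flagged missing contribute nothing; censored channels
    contribute according to ``method``.
    """
    if method is None:
        method = CensoringMethod("full_likelihood")
    pred_mean = np.asarray(pred_mean, dtype=float).reshape(-1)
    d = pred_mean.shape[0]
    pred_cov = np.asarray(pred_cov, dtype=float).reshape(d, d)
    y_row = np.array(y_row, dtype=float).reshape(len(channels))
    status_row = np.asarray(status_row, dtype=int).reshape(len(channels))
    thresholds_row = np.asarray(thresholds_row, dtype=float).reshape(len(channels))
    i_row = np.asarray(i_row, dtype=float).reshape(-1)

    if method.tag == "imputation":
        for j, ch in enumerate(channels):
            if status_row[j] == CENSORED:
                eta0 = ch.bias + ch.C @ pred_mean + (ch.D @ i_row if ch.D.size else 0.0)
                draws = [fam.sample_truncated_above(ch.kind, eta0, ch.dispersion,
                                                    thresholds_row[j], method.rng)
                         for _ in range(method.n_draws)]
                if ch.kind in ("lognormal", "gamma"):
                    y_star = math.exp(float(np.mean(np.log(draws))))
                else:
                    y_star = float(np.mean(draws))
                y_row[j] = y_star
                method.log.append((trial_index, ch.name, y_star))

    terms = _trial_terms(y_row, status_row, thresholds_row, channels, i_row, method)
    if not terms:
        return pred_mean.copy(), pred_cov.copy(), 0.0

    # conjugate Gaussian terms (observed normal / lognormal) fold in exactly
    # as sequential scalar Kalman updates; the rest are handled after.
    is_gauss = [t[2] in ("normal", "lognormal") and t[3][0] == "obs"
                for t in terms]
    gauss = [t for t, g in zip(terms, is_gauss) if g]
    nongauss = [t for t, g in zip(terms, is_gauss) if not g]
    mean = pred_mean.copy()
    cov = pred_cov.copy()
    ll = 0.0
    for C, off, kind, (_, y, disp) in gauss:
        z = math.log(y) if kind == "lognormal" else y
        Pc = cov @ C
        s = float(C @ Pc) + disp
        innov = z - (off + float(C @ mean))
        ll += -0.5 * (math.log(2.0 * math.pi * s) + innov * innov / s)
        if kind == "lognormal":
            ll -= z  # Jacobian of the log transform
        gain = Pc / s
        mean = mean + gain * innov
        cov = _sym(cov - np.outer(gain, Pc))

    if len(nongauss) == 1:
        C, off, kind, payload = nongauss[0]
        Pc = cov @ C
        s2 = float(C @ Pc)
        m_t = float(off + C @ mean)
        if s2 < 1e-13:
            # the state does not inform this term; likelihood shifts only
            ll += float(np.asarray(_term_loglik(kind, payload, m_t)[0]))
        else:
            mean_t, var_t, log_norm = _moment_match_1d(m_t, s2, kind, payload,
                                                       trial_index)
            gain = Pc / s2
            mean = mean + gain * (mean_t - m_t)
            cov = _sym(cov - np.outer(gain, gain) * (s2 - var_t))
            ll += log_norm
    elif len(nongauss) >= 2:
        # several non-Gaussian terms at once: joint Laplace (mode plus
        # curvature) by damped Newton in state space
        prec = _sym(_safe_inv(cov, "update_step"))
        base_mean = mean.copy()

        def objective(x):
            dx = x - base_mean
            f = -0.5 * dx @ prec @ dx
            g = -prec @ dx
            H = -prec.copy()
            for C, off, kind, payload in nongauss:
                eta = float(off + C @ x)
                llv, d1, d2 = _term_loglik(kind, payload, eta)
                f += llv
                g += d1 * C
                H += d2 * np.outer(C, C)
            return f, g, H

        x = base_mean.copy()
        f, g, H = objective(x)
        converged = np.linalg.norm(g) < NEWTON_GRAD_TOL
        for _ in range(NEWTON_MAX_ITER):
            if converged:
                break
            try:
                step = np.linalg.solve(-H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(-H + _JITTER * np.eye(d), g)
            t = 1.0
            for _ in range(40):
                x_new = x + t * step
                f_new, g_new, H_new = objective(x_new)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            else:
                raise NewtonError("step halving exhausted", trial=trial_index,
                                  last_iterate=x)
            x, f, g, H = x_new, f_new, g_new, H_new
            converged = np.linalg.norm(g) < NEWTON_GRAD_TOL
        if not converged:
            raise NewtonError(
                f"Newton did not converge in {NEWTON_MAX_ITER} iterations"
                + (f" (trial {trial_index + 1})" if trial_index is not None else ""),
                trial=trial_index, last_iterate=x)
        sign_p, logdet_p = np.linalg.slogdet(cov)
        sign_h, logdet_h = np.linalg.slogdet(-H)
        ll += f - 0.5 * logdet_p - 0.5 * logdet_h
        mean = x
        cov = _sym(_safe_inv(-H, "update_step posterior"))

    return mean, cov, float(ll)


def filter_pass(session: TrialSession, spec: ModelSpec,
                method: CensoringMethod | None = None) -> PosteriorTrajectory:
    """Forward predict/update sweep over all trials of a session."""
    if method is None:
        method = CensoringMethod("full_likelihood")
    st = spec.state
    K, d = session.K, st.d
    x_pred = np.zeros((K, d))
    P_pred = np.zeros((K, d, d))
    x_filt = np.zeros((K, d))
    P_filt = np.zeros((K, d, d))
    ll = np.zeros(K)
    mean, cov = st.x0.copy(), st.P0.copy()
    for k in range(K):
        if k > 0:
            mean, cov = predict_step(x_filt[k - 1], P_filt[k - 1],
                                     session.U[k - 1], st)
        x_pred[k], P_pred[k] = mean, cov
        x_filt[k], P_filt[k], ll[k] = update_step(
            mean, cov, session.Y[k], session.status[k], session.thresholds[k],
            spec.channels, session.I[k], method=method, trial_index=k)
    return PosteriorTrajectory(x_pred, P_pred, x_filt, P_filt, ll)


def smoother_pass(traj: PosteriorTrajectory, spec: ModelSpec) -> PosteriorTrajectory:
    """Add fixed-interval (RTS) smoothed moments and lag-one covariances."""
    st = spec.state
    K, d = traj.K, st.d
    x_s = np.zeros((K, d))
    P_s = np.zeros((K, d, d))
    P_lag = np.full((K, d, d), np.nan)
    if K == 0:
        traj.x_smooth, traj.P_smooth, traj.P_lag = x_s, P_s, P_lag
        return traj
    x_s[K - 1] = traj.x_filt[K - 1]
    P_s[K - 1] = traj.P_filt[K - 1]
    J_prev = None
    for k in range(K - 2, -1, -1):
        P_pred_next = traj.P_pred[k + 1]
        J = traj.P_filt[k] @ st.A.T @ _safe_inv(P_pred_next, "smoother_pass")
        x_s[k] = traj.x_filt[k] + J @ (x_s[k + 1] - traj.x_pred[k + 1])
        P_s[k] = _sym(traj.P_filt[k] + J @ (P_s[k + 1] - P_pred_next) @ J.T)
        # Cov(x_{k+1}, x_k | Y) via the smoother-gain identity
        P_lag[k + 1] = P_s[k + 1] @ J.T
    traj.x_smooth, traj.P_smooth, traj.P_lag = x_s, P_s, P_lag
    return traj


class OnlineFilter:
    """Streaming filter: consume trials one at a time, emit the posterior.

    Feeding a whole session trial-by-trial reproduces :func:`filter_pass`
    exactly; the model spec may be swapped mid-stream (e.g., after a
    periodic re-fit) and the stream resumes from the current belief.
    """

    def __init__(self, spec: ModelSpec, method: CensoringMethod | None = None):
        self.spec = spec
        self.method = method if method is not None else CensoringMethod("full_likelihood")
        self._mean = spec.state.x0.copy()
        self._cov = spec.state.P0.copy()
        self._prev_u = None
        self._k = 0
        self.loglik = 0.0

    def update_spec(self, spec: ModelSpec):
        """Swap model parameters without resetting the state belief."""
        self.spec = spec

    def step(self, y_row, u_row=(), i_row=(), status_row=None, thresholds_row=None):
        """Consume one trial; return (filtered mean, filtered covariance)."""
        ch = self.spec.channels
        if status_row is None:
            status_row = np.full(len(ch), OBSERVED, dtype=int)
        if thresholds_row is None:
            thresholds_row = np.full(len(ch), np.nan)
        if self._k > 0:
            self._mean, self._cov = predict_step(self._mean, self._cov,
                                                 self._prev_u, self.spec.state)
        mean, cov, ll = update_step(self._mean, self._cov, y_row, status_row,
                                    thresholds_row, ch, i_row,
                                    method=self.method, trial_index=self._k)
        self._mean, self._cov = mean, cov
        self._prev_u = np.asarray(u_row, dtype=float).reshape(self.spec.state.p)
        self._k += 1
        self.loglik += ll
        return mean.copy(), cov.copy()


def online_filter(stream, spec: ModelSpec, method: CensoringMethod | None = None):
    """Generator over (filtered mean, filtered covariance) per consumed trial.

    ``stream`` yields (y_row, u_row, i_row, status_row, thresholds_row)
    tuples; trailing elements may be omitted.
    """
    of = OnlineFilter(spec, method)
    for item in stream:
        yield of.step(*item)


def trajectory_frame(traj: PosteriorTrajectory, spec: ModelSpec) -> pd.DataFrame:
    """Tabulate a trajectory, one row per trial (1-based), for CSV export.

    Covariances are flattened upper triangles (var.<i>.<j> columns).
    """
    K, d = traj.K, spec.state.d
    cols = {"trial": np.arange(1, K + 1)}
    for i in range(d):
        cols[f"x_pred.{i}"] = traj.x_pred[:, i]
    for i in range(d):
        cols[f"x_filt.{i}"] = traj.x_filt[:, i]
    if traj.x_smooth is not None:
        for i in range(d):
            cols[f"x_smooth.{i}"] = traj.x_smooth[:, i]
    for i in range(d):
        for j in range(i, d):
            cols[f"var_filt.{i}.{j}"] = traj.P_filt[:, i, j]
    if traj.P_smooth is not None:
        for i in range(d):
            for j in range(i, d):
                cols[f"var_smooth.{i}.{j}"] = traj.P_smooth[:, i, j]
    cols["loglik"] = traj.loglik_trials
    return pd.DataFrame(cols)
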