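"""Treatments of observations censored from above.

A censored trial tells us only that the readout exceeded a known threshold
(for example, the subject failed to respond within the response window, so
the reaction time exceeded it).  Three treatments are supported, selected
by a :class:`CensoringMethod` tag:

``mar``
    Treat censored entries as missing at random: drop them from the
    likelihood entirely.  This discards the information that the readout
    was large and biases state estimates away from the slow tail.
``imputation``
    Replace each censored entry with a draw from the channel's predictive
    distribution at the one-step predicted state, truncated to
    (threshold, inf), then proceed as if it had been observed.
``full_likelihood``
    Use the exact censored-data likelihood contribution
    log S(threshold | eta) = log P(Y > threshold | eta) in the filter's
    Newton objective and the M-step, with analytic derivatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .model import CONTINUOUS_KINDS, ObservationChannel, linear_predictor

__all__ = ["METHODS", "CensoringMethod", "censored_loglik_term",
           "censored_eta_terms", "mar_update", "imputation_update",
           "full_likelihood_update"]

METHODS = ("mar", "imputation", "full_likelihood")


@dataclass
class CensoringMethod:
    """Censoring treatment tag plus the imputation RNG bookkeeping."""

    tag: str = "full_likelihood"
    seed: int | None = None
    n_draws: int = 1
    log: list = field(default_factory=list)   # (trial, channel, draw) audit trail

    def __post_init__(self):
        if self.tag not in METHODS:
            raise ValueError(f"unknown censoring method {self.tag!r}; valid: {METHODS}")
        self._rng = np.random.default_rng(self.seed)

    def reset_rng(self):
        """Rewind the imputation stream (used when re-running a fit pass)."""
        self._rng = np.random.default_rng(self.seed)
        self.log.clear()

    @property
    def rng(self) -> np.random.Generator:
        return self._rng


def censored_eta_terms(kind: str, threshold: float, eta, disp):
    """(log S, dlogS/deta, d2logS/deta2) at a given linear predictor.

    S is the survival function P(Y > threshold | eta): Gaussian survival of
    (threshold - eta)/sigma for normal (on log threshold for lognormal),
    and the upper regularized incomplete gamma Q(nu, nu*threshold*e^-eta)
    for gamma.  Derivatives are analytic Mills-ratio forms, finite for all
    finite inputs; scalar or array eta is accepted.
    """
    eta = np.asarray(eta, dtype=float)
    threshold = np.asarray(threshold, dtype=float)
    if kind in ("normal", "lognormal"):
        t = np.log(threshold) if kind == "lognormal" else threshold
        sd = math.sqrt(disp)
        z = (eta - t) / sd
        log_s = special.log_ndtr(z)
        # inverse Mills ratio phi(z)/Phi(z), stable in the deep tail
        r = np.exp(-0.5 * z * z - 0.5 * math.log(2.0 * math.pi) - log_s)
        d1 = r / sd
        d2 = (-z * r - r * r) / disp
    elif kind == "gamma":
        nu = disp
        s = nu * threshold * np.exp(-eta)  # threshold broadcasts over eta
        q = special.gammaincc(nu, s)
        log_s = np.log(np.maximum(q, 1e-300))
        # d/deta log Q = s^nu e^-s / (Gamma(nu) Q)
        with np.errstate(divide="ignore", invalid="ignore"):
            d1 = np.where(s > 0,
                          np.exp(nu * np.log(np.maximum(s, 1e-300)) - s
                                 - special.gammaln(nu) - log_s),
                          0.0)
        d2 = d1 * (s - nu - d1)
    else:
        raise ValueError(f"censoring unsupported for kind {kind!r}")
    if log_s.ndim == 0:
        return float(log_s), float(d1), float(d2)
    return log_s, d1, d2


def censored_loglik_term(channel: ObservationChannel, threshold: float, x,
                         i_row=()):
    """Survival log-likelihood term of a censored observation at state x."""
    if channel.kind not in CONTINUOUS_KINDS:
        raise ValueError(
            f"channel {channel.name!r}: kind {channel.kind!r} cannot be censored")
    eta = linear_predictor(channel, x, i_row)
    return censored_eta_terms(channel.kind, threshold, eta, channel.dispersion)


def _dispatch_update(method_tag, *args, **kwargs):
    from . import inference
    return inference.update_step(*args, method=CensoringMethod(method_tag), **kwargs)


def mar_update(pred_mean, pred_cov, y_row, status_row, thresholds_row, channels,
               i_row=()):
    """One filter update with censored entries treated as dropped at random."""
    return _dispatch_update("mar", pred_mean, pred_cov, y_row, status_row,
                            thresholds_row, channels, i_row)


def imputation_update(pred_mean, pred_cov, y_row, status_row, thresholds_row,
                      channels, i_row=(), rng=None, method=None):
    """One filter update with censored entries replaced by truncated draws."""
    from . import inference
    if method is None:
        method = CensoringMethod("imputation")
        if rng is not None:
            method._rng = rng
    return inference.update_step(pred_mean, pred_cov, y_row, status_row,
                                 thresholds_row, channels, i_row, method=method)


def full_likelihood_update(pred_mean, pred_cov, y_row, status_row,
                           thresholds_row, channels, i_row=()):
    """One filter update carrying the censored survival term exactly."""
    return _dispatch_update("full_likelihood", pred_mean, pred_cov, y_row,
                            status_row, thresholds_row, channels, i_row)
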