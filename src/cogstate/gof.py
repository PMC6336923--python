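"""Model comparison and parameter-uncertainty diagnostics.

Deviance is -2 times the (Laplace-approximate) marginal log-likelihood
from the forward filter; AIC and BIC follow from the free-parameter
census.  The parameter covariance is the inverse of the observed
information, computed by central finite differences of the log-likelihood
over the free-parameter vector — a method-agnostic choice that works
identically for all channel families and censoring treatments.  Standard
errors and 95% Wald intervals come from the (PSD-projected) covariance
diagonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._params import get_free_params, set_free_params
from .censoring import CensoringMethod
from .inference import filter_pass
from .model import ModelSpec, TrialSession

__all__ = ["FitDiagnostics", "deviance", "information_criteria",
           "param_covariance", "n_free_params"]

FD_REL_STEP = 1e-4
Z_95 = 1.959963984540054


@dataclass
class FitDiagnostics:
    """Deviance-based criteria plus Wald-type parameter uncertainty."""

    deviance: float
    aic: float
    bic: float
    n_free: int
    n_trials: int
    labels: list
    covariance: np.ndarray
    se: np.ndarray
    wald_lower: np.ndarray
    wald_upper: np.ndarray
    psd_projected: bool = False

    def table(self) -> str:
        """Human-readable summary."""
        _, est = None, None
        lines = [f"deviance = {self.deviance:.4f}   "
                 f"AIC = {self.aic:.4f}   BIC = {self.bic:.4f}   "
                 f"(free parameters: {self.n_free}, trials: {self.n_trials})"]
        if self.labels:
            w = max(len(l) for l in self.labels)
            lines.append(f"{'parameter':<{w}}  {'SE':>12}  {'95% CI':>28}")
            for i, lab in enumerate(self.labels):
                lines.append(f"{lab:<{w}}  {self.se[i]:12.5g}  "
                             f"[{self.wald_lower[i]:12.5g}, {self.wald_upper[i]:12.5g}]")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "deviance": self.deviance, "aic": self.aic, "bic": self.bic,
            "n_free": self.n_free, "n_trials": self.n_trials,
            "labels": list(self.labels),
            "covariance": np.asarray(self.covariance).tolist(),
            "se": np.asarray(self.se).tolist(),
            "wald_lower": np.asarray(self.wald_lower).tolist(),
            "wald_upper": np.asarray(self.wald_upper).tolist(),
            "psd_projected": self.psd_projected,
        }


def n_free_params(spec: ModelSpec) -> int:
    return len(get_free_params(spec)[0])


def deviance(session: TrialSession, spec: ModelSpec,
             method: CensoringMethod | None = None) -> float:
    """-2 x total marginal log-likelihood of the session under the spec."""
    if session.K == 0:
        return 0.0
    return -2.0 * filter_pass(session, spec, method).loglik


def information_criteria(session: TrialSession, spec: ModelSpec,
                         method: CensoringMethod | None = None):
    """(deviance, AIC, BIC) with the free-parameter census as k."""
    dev = deviance(session, spec, method)
    k = n_free_params(spec)
    K = max(session.K, 1)
    return dev, dev + 2.0 * k, dev + k * math.log(K)


def _loglik_at(theta, session, spec, method):
    trial_spec = set_free_params(spec, theta)
    if method is not None and method.tag == "imputation":
        method = CensoringMethod("imputation", seed=method.seed,
                                 n_draws=method.n_draws)
    return filter_pass(session, trial_spec, method).loglik


def param_covariance(session: TrialSession, spec: ModelSpec,
                     method: CensoringMethod | None = None,
                     rel_step: float = FD_REL_STEP) -> FitDiagnostics:
    """Observed-information covariance of the free parameters at the MLE.

    The Hessian of the negative log-likelihood is formed by central finite
    differences with a relative step (adaptive floor for near-zero
    parameters), inverted, and projected to the nearest PSD matrix if any
    eigenvalue is negative (flagged on the result).
    """
    labels, theta = get_free_params(spec)
    n = theta.shape[0]
    dev, aic, bic = information_criteria(session, spec, method)
    if n == 0:
        z = np.zeros((0,))
        return FitDiagnostics(dev, aic, bic, 0, session.K, [], np.zeros((0, 0)),
                              z, z, z)
    steps = rel_step * np.maximum(np.abs(theta), 1e-2)

    def f(t):
        return _loglik_at(t, session, spec, method)

    H = np.zeros((n, n))
    f0 = f(theta)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        for j in range(i, n):
            ej = np.zeros(n)
            ej[j] = steps[j]
            if i == j:
                val = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / steps[i] ** 2
            else:
                val = (f(theta + ei + ej) - f(theta + ei - ej)
                       - f(theta - ei + ej) + f(theta - ei - ej)) \
                      / (4.0 * steps[i] * steps[j])
            H[i, j] = H[j, i] = val
    info = -H  # observed information
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    cov = 0.5 * (cov + cov.T)
    projected = False
    w, V = np.linalg.eigh(cov)
    if w.min() < 0:
        projected = True
        w = np.clip(w, 0.0, None)
        cov = V @ np.diag(w) @ V.T
    var = np.diag(cov).copy()
    if (var < -1e-12).any():
        raise np.linalg.LinAlgError(
            "indefinite observed information even after PSD projection; "
            "the spec is likely not at a maximum of the likelihood")
    se = np.sqrt(np.clip(var, 0.0, None))
    return FitDiagnostics(dev, aic, bic, n, session.K, labels, cov, se,
                          theta - Z_95 * se, theta + Z_95 * se,
                          psd_projected=projected)
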