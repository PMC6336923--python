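"""Per-family observation densities as functions of the linear predictor.

Every family is expressed through eta = bias + C x + D i with its canonical
link fixed by the package: logistic for bernoulli/point_process, log link
for gamma mean and lognormal location, identity for normal.  All derivative
helpers return derivatives with respect to eta and accept scalar or array
eta, which the filter and the M-step map onto state or coefficient space
via the chain rule.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special, stats

LOG2PI = math.log(2.0 * math.pi)


def loglik(kind: str, y, eta, disp):
    """Log density of one observation given its linear predictor."""
    eta = np.asarray(eta, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind in ("bernoulli", "point_process"):
        out = y * eta - np.logaddexp(0.0, eta)
    elif kind == "normal":
        out = -0.5 * (LOG2PI + math.log(disp)) - (y - eta) ** 2 / (2.0 * disp)
    elif kind == "lognormal":
        z = np.log(y)
        out = (-0.5 * (LOG2PI + math.log(disp)) - z
               - (z - eta) ** 2 / (2.0 * disp))
    elif kind == "gamma":
        nu = disp
        out = (nu * (math.log(nu) - eta) + (nu - 1.0) * np.log(y)
               - nu * y * np.exp(-eta) - special.gammaln(nu))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def dloglik(kind: str, y, eta, disp):
    """(d/deta, d2/deta2) of the log density."""
    eta = np.asarray(eta, dtype=float)
    if kind in ("bernoulli", "point_process"):
        p = special.expit(eta)
        d1, d2 = y - p, -p * (1.0 - p)
    elif kind == "normal":
        d1 = (np.asarray(y, dtype=float) - eta) / disp
        d2 = np.broadcast_to(np.asarray(-1.0 / disp), d1.shape).copy()
    elif kind == "lognormal":
        d1 = (np.log(y) - eta) / disp
        d2 = np.broadcast_to(np.asarray(-1.0 / disp), d1.shape).copy()
    elif kind == "gamma":
        nu = disp
        w = nu * y * np.exp(-eta)
        d1, d2 = w - nu, -w
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if np.ndim(d1) == 0:
        return float(d1), float(d2)
    return d1, d2


def mean(kind: str, eta: float, disp) -> float:
    """Expected observation value at a given linear predictor."""
    if kind in ("bernoulli", "point_process"):
        return float(special.expit(eta))
    if kind == "normal":
        return eta
    if kind == "lognormal":
        return math.exp(eta + disp / 2.0)
    if kind == "gamma":
        return math.exp(eta)
    raise ValueError(f"unknown kind {kind!r}")


def sample(kind: str, eta, disp, rng: np.random.Generator):
    """Draw from the family at linear predictor eta (vectorized over eta)."""
    eta = np.asarray(eta, dtype=float)
    if kind in ("bernoulli", "point_process"):
        return (rng.random(eta.shape) < special.expit(eta)).astype(float)
    if kind == "normal":
        return rng.normal(eta, math.sqrt(disp))
    if kind == "lognormal":
        return np.exp(rng.normal(eta, math.sqrt(disp)))
    if kind == "gamma":
        nu = disp
        return rng.gamma(shape=nu, scale=np.exp(eta) / nu, size=eta.shape)
    raise ValueError(f"unknown kind {kind!r}")


def log_sf(kind: str, threshold: float, eta, disp):
    """log P(Y > threshold | eta) for continuous kinds (vectorized)."""
    eta = np.asarray(eta, dtype=float)
    if kind == "normal":
        out = special.log_ndtr((eta - threshold) / math.sqrt(disp))
    elif kind == "lognormal":
        out = special.log_ndtr((eta - math.log(threshold)) / math.sqrt(disp))
    elif kind == "gamma":
        nu = disp
        s = nu * threshold * np.exp(-eta)
        out = np.log(np.maximum(special.gammaincc(nu, s), 1e-300))
    else:
        raise ValueError(f"censoring unsupported for kind {kind!r}")
    return float(out) if out.ndim == 0 else out


def sample_truncated_above(kind: str, eta: float, disp, threshold: float,
                           rng: np.random.Generator) -> float:
    """Inverse-CDF draw from the family truncated to (threshold, inf)."""
    u = rng.random()
    if kind in ("normal", "lognormal"):
        sd = math.sqrt(disp)
        t = threshold if kind == "normal" else math.log(threshold)
        log_tail = stats.norm.logsf(t, loc=eta, scale=sd)
        if log_tail < math.log(1e-12):
            raise ValueError(
                f"truncated mass {math.exp(log_tail):.3g} below threshold tolerance")
        # draw uniformly within the upper tail via the inverse survival function
        q = math.exp(log_tail) * u
        z = stats.norm.isf(q, loc=eta, scale=sd)
        draw = z if kind == "normal" else math.exp(z)
        return float(max(draw, threshold * (1.0 + 1e-12)))
    if kind == "gamma":
        nu = disp
        scale = math.exp(eta) / nu
        tail = stats.gamma.sf(threshold, a=nu, scale=scale)
        if tail < 1e-12:
            raise ValueError(f"truncated mass {tail:.3g} below threshold tolerance")
        draw = stats.gamma.isf(tail * u, a=nu, scale=scale)
        return float(max(draw, threshold * (1.0 + 1e-12)))
    raise ValueError(f"censoring unsupported for kind {kind!r}")
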