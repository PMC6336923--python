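"""Model declaration, validation, and serialization.

A model couples linear-Gaussian latent dynamics

    x[k+1] = A x[k] + B u[k] + w[k],   w[k] ~ N(0, Q),   x[1] ~ N(x0, P0)

with one or more observation channels.  Each channel maps the state and
per-trial covariates through a linear predictor

    eta = bias + C x + D i

into a distribution over the behavioral readout: Bernoulli (logistic link)
for binary choices and per-bin spike indicators, log-normal or gamma
(log link) for skewed positive data such as reaction times, or normal
(identity link).  Every parameter carries an elementwise boolean mask:
True marks a free parameter that estimation may move, False pins it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "KINDS",
    "CONTINUOUS_KINDS",
    "OBSERVED",
    "MISSING",
    "CENSORED",
    "STATUS_LABELS",
    "StateModel",
    "ObservationChannel",
    "ModelSpec",
    "TrialSession",
    "validate_spec",
    "linear_predictor",
    "serialize_spec",
    "parse_spec",
    "read_session_csv",
    "write_session_csv",
]

KINDS = ("normal", "lognormal", "gamma", "bernoulli", "point_process")
CONTINUOUS_KINDS = ("normal", "lognormal", "gamma")
DISPERSION_KINDS = ("normal", "lognormal", "gamma")

# per-observation status codes
OBSERVED, MISSING, CENSORED = 0, 1, 2
STATUS_LABELS = {OBSERVED: "observed", MISSING: "missing", CENSORED: "censored"}
STATUS_CODES = {v: k for k, v in STATUS_LABELS.items()}


def _as_matrix(x, rows, cols, dtype=float):
    a = np.asarray(x, dtype=dtype)
    return a.reshape(rows, cols)


@dataclass
class StateModel:
    """Latent linear-Gaussian dynamics and their free/fixed masks."""

    A: np.ndarray
    B: np.ndarray
    Q: np.ndarray
    x0: np.ndarray
    P0: np.ndarray
    mask_A: np.ndarray = None
    mask_B: np.ndarray = None
    mask_Q: np.ndarray = None
    mask_x0: np.ndarray = None
    mask_P0: np.ndarray = None

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        d = self.A.shape[0]
        self.B = _as_matrix(self.B, d, -1) if np.size(self.B) else np.zeros((d, 0))
        self.Q = _as_matrix(self.Q, d, d)
        self.x0 = np.asarray(self.x0, dtype=float).reshape(d)
        self.P0 = _as_matrix(self.P0, d, d)
        for name, default in (
            ("mask_A", True), ("mask_B", True), ("mask_Q", True),
            ("mask_x0", False), ("mask_P0", False),
        ):
            ref = {"mask_A": self.A, "mask_B": self.B, "mask_Q": self.Q,
                   "mask_x0": self.x0, "mask_P0": self.P0}[name]
            m = getattr(self, name)
            if m is None:
                m = np.full(ref.shape, default, dtype=bool)
            else:
                m = np.asarray(m, dtype=bool).reshape(ref.shape)
            setattr(self, name, m)

    @property
    def d(self) -> int:
        return self.A.shape[0]

    @property
    def p(self) -> int:
        return self.B.shape[1]

    def copy(self) -> "StateModel":
        return StateModel(
            self.A.copy(), self.B.copy(), self.Q.copy(),
            self.x0.copy(), self.P0.copy(),
            self.mask_A.copy(), self.mask_B.copy(), self.mask_Q.copy(),
            self.mask_x0.copy(), self.mask_P0.copy(),
        )


@dataclass
class ObservationChannel:
    """One behavioral readout: distribution family plus linear predictor.

    ``dispersion`` is the log-scale variance sigma^2 for normal/lognormal
    and the shape nu for gamma; Bernoulli-family channels carry none.
    ``censorable`` marks channels whose observations may be censored from
    above (only meaningful for continuous kinds).
    """

    name: str
    kind: str
    bias: float = 0.0
    C: np.ndarray = ()
    D: np.ndarray = ()
    dispersion: float | None = None
    censorable: bool = False
    mask_bias: bool = True
    mask_C: np.ndarray = None
    mask_D: np.ndarray = None
    mask_dispersion: bool = True

    def __post_init__(self):
        self.bias = float(self.bias)
        self.C = np.asarray(self.C, dtype=float).reshape(-1)
        self.D = np.asarray(self.D, dtype=float).reshape(-1)
        if self.dispersion is not None:
            self.dispersion = float(self.dispersion)
        self.censorable = bool(self.censorable)
        self.mask_bias = bool(self.mask_bias)
        if self.mask_C is None:
            self.mask_C = np.ones(self.C.shape, dtype=bool)
        else:
            self.mask_C = np.asarray(self.mask_C, dtype=bool).reshape(self.C.shape)
        if self.mask_D is None:
            self.mask_D = np.ones(self.D.shape, dtype=bool)
        else:
            self.mask_D = np.asarray(self.mask_D, dtype=bool).reshape(self.D.shape)
        self.mask_dispersion = bool(self.mask_dispersion)

    @property
    def has_dispersion(self) -> bool:
        return self.kind in DISPERSION_KINDS

    def copy(self) -> "ObservationChannel":
        return ObservationChannel(
            self.name, self.kind, self.bias, self.C.copy(), self.D.copy(),
            self.dispersion, self.censorable, self.mask_bias,
            self.mask_C.copy(), self.mask_D.copy(), self.mask_dispersion,
        )


@dataclass
class ModelSpec:
    """Full generative model: state dynamics plus an ordered channel list."""

    state: StateModel
    channels: list

    @property
    def channel_names(self):
        return [c.name for c in self.channels]

    @property
    def m(self) -> int:
        return len(self.channels)

    def copy(self) -> "ModelSpec":
        return ModelSpec(self.state.copy(), [c.copy() for c in self.channels])


@dataclass
class TrialSession:
    """K trials of observations, inputs, covariates, and status flags.

    Y is K x m (one column per channel, units per channel), U is K x p
    inputs driving the state, I is K x q covariates entering the linear
    predictors (lagged-observation history columns go here too).
    ``status`` holds the per-observation codes OBSERVED / MISSING /
    CENSORED; ``thresholds`` holds the censoring threshold wherever
    status == CENSORED (NaN elsewhere).
    """

    Y: np.ndarray
    U: np.ndarray = None
    I: np.ndarray = None
    status: np.ndarray = None
    thresholds: np.ndarray = None

    def __post_init__(self):
        Y = np.asarray(self.Y, dtype=float)
        self.Y = Y if Y.ndim == 2 else np.atleast_2d(Y)
        K, m = self.Y.shape

        def cols(a):
            if a is None:
                return np.zeros((K, 0))
            a = np.asarray(a, dtype=float)
            return a.reshape(K, -1) if a.size else a.reshape(K, 0)

        self.U = cols(self.U)
        self.I = cols(self.I)
        if self.status is None:
            self.status = np.full((K, m), OBSERVED, dtype=int)
        else:
            self.status = np.asarray(self.status, dtype=int).reshape(K, m)
        if self.thresholds is None:
            self.thresholds = np.full((K, m), np.nan)
        else:
            self.thresholds = np.asarray(self.thresholds, dtype=float).reshape(K, m)

    @property
    def K(self) -> int:
        return self.Y.shape[0]

    def rows(self):
        """Iterate (y, u, i, status, thresholds) per trial."""
        for k in range(self.K):
            yield (self.Y[k], self.U[k], self.I[k],
                   self.status[k], self.thresholds[k])


def linear_predictor(channel: ObservationChannel, x, i_row=()) -> float:
    """Systematic component eta = bias + C.x + D.i of a channel.

    The event probability of a Bernoulli-family channel is ``expit(eta)``;
    log-normal places log Y ~ N(eta, sigma^2); gamma has mean exp(eta);
    normal has mean eta.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    i_row = np.asarray(i_row, dtype=float).reshape(-1)
    if x.shape[0] != channel.C.shape[0]:
        raise ValueError(
            f"channel {channel.name!r}: state dim {x.shape[0]} != C dim {channel.C.shape[0]}")
    if i_row.shape[0] != channel.D.shape[0]:
        raise ValueError(
            f"channel {channel.name!r}: covariate dim {i_row.shape[0]} != D dim {channel.D.shape[0]}")
    return float(channel.bias + channel.C @ x + channel.D @ i_row)


def event_probability(channel: ObservationChannel, x, i_row=()) -> float:
    """Bernoulli event probability logistic(eta)."""
    return float(expit(linear_predictor(channel, x, i_row)))


def _is_psd(M, tol=1e-10):
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        return False
    w = np.linalg.eigvalsh(0.5 * (M + M.T))
    return bool(w.min() >= -tol * max(1.0, abs(w.max())))


def validate_spec(spec: ModelSpec) -> list:
    """Return every structural violation as a human-readable string.

    An empty list means the spec can be simulated and fitted.
    """
    out = []
    st = spec.state
    d = st.d
    if st.A.shape != (d, d):
        out.append(f"state.A: expected ({d},{d}), got {st.A.shape}")
    if st.Q.shape != (d, d):
        out.append(f"state.Q: expected ({d},{d}), got {st.Q.shape}")
    elif not _is_psd(st.Q):
        out.append("state.Q: not symmetric positive semi-definite")
    if st.P0.shape != (d, d):
        out.append(f"state.P0: expected ({d},{d}), got {st.P0.shape}")
    elif not _is_psd(st.P0):
        out.append("state.P0: not symmetric positive semi-definite")
    if st.B.shape[0] != d:
        out.append(f"state.B: expected {d} rows, got {st.B.shape[0]}")
    if st.x0.shape != (d,):
        out.append(f"state.x0: expected length {d}, got {st.x0.shape}")
    if not spec.channels:
        out.append("channels: at least one observation channel is required")
    names = [c.name for c in spec.channels]
    if len(set(names)) != len(names):
        out.append("channels: duplicate channel names")
    for c in spec.channels:
        loc = f"channel {c.name!r}"
        if c.kind not in KINDS:
            out.append(f"{loc}: unknown kind {c.kind!r} (valid: {', '.join(KINDS)})")
            continue
        if c.C.shape[0] != d:
            out.append(f"{loc}: C has length {c.C.shape[0]}, state dimension is {d}")
        if c.has_dispersion:
            if c.dispersion is None:
                out.append(f"{loc}: kind {c.kind!r} requires a dispersion")
            elif not c.dispersion > 0:
                out.append(f"{loc}: dispersion must be > 0, got {c.dispersion}")
        elif c.dispersion is not None:
            out.append(f"{loc}: kind {c.kind!r} takes no dispersion")
        if c.censorable and c.kind not in CONTINUOUS_KINDS:
            out.append(f"{loc}: censorable only permitted for continuous kinds")
    return out


def validate_session(session: TrialSession, spec: ModelSpec) -> list:
    """Check a session's shapes, status flags, and thresholds against a spec."""
    out = []
    if session.Y.shape[1] != spec.m:
        out.append(f"Y: {session.Y.shape[1]} columns for {spec.m} channels")
        return out
    if session.U.shape[1] != spec.state.p:
        out.append(f"U: {session.U.shape[1]} columns, state.B expects {spec.state.p}")
    q = max((c.D.shape[0] for c in spec.channels), default=0)
    if session.I.shape[1] < q:
        out.append(f"I: {session.I.shape[1]} columns, channels need {q}")
    for j, c in enumerate(spec.channels):
        cens = session.status[:, j] == CENSORED
        if cens.any() and not c.censorable:
            out.append(f"channel {c.name!r}: censored flags on a non-censorable channel")
        thr = session.thresholds[cens.nonzero()[0], j] if cens.any() else np.array([])
        if thr.size and not (np.isfinite(thr).all() and (thr > 0).all()):
            out.append(f"channel {c.name!r}: censored trials need finite positive thresholds")
        obs = session.status[:, j] == OBSERVED
        if c.kind in ("lognormal", "gamma") and obs.any():
            y = session.Y[obs, j]
            if not (y > 0).all():
                out.append(f"channel {c.name!r}: {c.kind} requires strictly positive observations")
    bad = ~np.isin(session.status, (OBSERVED, MISSING, CENSORED))
    if bad.any():
        out.append("status: codes outside {observed, missing, censored}")
    return out


# ---------------------------------------------------------------------------
# serialization (YAML config dialect)

_STATE_FIELDS = ("A", "B", "Q", "x0", "P0", "mask_A", "mask_B", "mask_Q",
                 "mask_x0", "mask_P0")
_CHANNEL_FIELDS = ("name", "kind", "bias", "C", "D", "dispersion", "censorable",
                   "mask_bias", "mask_C", "mask_D", "mask_dispersion")


def _arr_out(a):
    return np.asarray(a).tolist()


def serialize_spec(spec: ModelSpec) -> str:
    """Render a spec as a YAML document; ``parse_spec`` inverts it exactly."""
    st = spec.state
    doc = {
        "state": {
            "A": _arr_out(st.A), "B": _arr_out(st.B), "Q": _arr_out(st.Q),
            "x0": _arr_out(st.x0), "P0": _arr_out(st.P0),
            "mask_A": _arr_out(st.mask_A), "mask_B": _arr_out(st.mask_B),
            "mask_Q": _arr_out(st.mask_Q), "mask_x0": _arr_out(st.mask_x0),
            "mask_P0": _arr_out(st.mask_P0),
        },
        "channels": [
            {
                "name": c.name, "kind": c.kind, "bias": float(c.bias),
                "C": _arr_out(c.C), "D": _arr_out(c.D),
                "dispersion": None if c.dispersion is None else float(c.dispersion),
                "censorable": bool(c.censorable),
                "mask_bias": bool(c.mask_bias),
                "mask_C": _arr_out(c.mask_C), "mask_D": _arr_out(c.mask_D),
                "mask_dispersion": bool(c.mask_dispersion),
            }
            for c in spec.channels
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)


class SpecParseError(ValueError):
    pass


def _check_fields(mapping, allowed, where):
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise SpecParseError(f"{where}: unknown field(s) {sorted(unknown)}")


def parse_spec(text: str) -> ModelSpec:
    """Parse a YAML model config; unknown fields and kinds are errors."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise SpecParseError(f"malformed config: {e}") from e
    if not isinstance(doc, dict):
        raise SpecParseError("config must be a mapping with 'state' and 'channels'")
    _check_fields(doc, ("state", "channels"), "top level")
    if "state" not in doc or "channels" not in doc:
        raise SpecParseError("config requires both 'state' and 'channels'")
    sd = doc["state"]
    _check_fields(sd, _STATE_FIELDS, "state")
    missing = [f for f in ("A", "Q", "x0", "P0") if f not in sd]
    if missing:
        raise SpecParseError(f"state: missing field(s) {missing}")
    state = StateModel(
        A=sd["A"], B=sd.get("B", []), Q=sd["Q"], x0=sd["x0"], P0=sd["P0"],
        mask_A=sd.get("mask_A"), mask_B=sd.get("mask_B"), mask_Q=sd.get("mask_Q"),
        mask_x0=sd.get("mask_x0"), mask_P0=sd.get("mask_P0"),
    )
    channels = []
    for idx, cd in enumerate(doc["channels"]):
        where = f"channels[{idx}]"
        _check_fields(cd, _CHANNEL_FIELDS, where)
        if "kind" not in cd:
            raise SpecParseError(f"{where}: missing 'kind'")
        if cd["kind"] not in KINDS:
            raise SpecParseError(
                f"{where}: unknown kind {cd['kind']!r}; valid kinds: {', '.join(KINDS)}")
        channels.append(ObservationChannel(
            name=cd.get("name", f"y{idx}"), kind=cd["kind"],
            bias=cd.get("bias", 0.0), C=cd.get("C", ()), D=cd.get("D", ()),
            dispersion=cd.get("dispersion"), censorable=cd.get("censorable", False),
            mask_bias=cd.get("mask_bias", True), mask_C=cd.get("mask_C"),
            mask_D=cd.get("mask_D"), mask_dispersion=cd.get("mask_dispersion", True),
        ))
    return ModelSpec(state=state, channels=channels)


# ---------------------------------------------------------------------------
# session CSV I/O: one row per trial, columns y.<ch>, u.<j>, i.<j>,
# status.<ch>, threshold.<ch>; trials reported 1-based.

def write_session_csv(session: TrialSession, spec: ModelSpec, path_or_buf,
                      header_comment: str | None = None):
    cols = {"trial": np.arange(1, session.K + 1)}
    for j, name in enumerate(spec.channel_names):
        cols[f"y.{name}"] = session.Y[:, j]
    for j in range(session.U.shape[1]):
        cols[f"u.{j}"] = session.U[:, j]
    for j in range(session.I.shape[1]):
        cols[f"i.{j}"] = session.I[:, j]
    for j, name in enumerate(spec.channel_names):
        cols[f"status.{name}"] = [STATUS_LABELS[s] for s in session.status[:, j]]
        cols[f"threshold.{name}"] = session.thresholds[:, j]
    df = pd.DataFrame(cols)
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_session_csv(path_or_buf, spec: ModelSpec) -> TrialSession:
    df = pd.read_csv(path_or_buf, comment="#")
    K = len(df)
    names = spec.channel_names
    missing_cols = [f"y.{n}" for n in names if f"y.{n}" not in df.columns]
    if missing_cols:
        raise ValueError(f"session is missing column(s): {missing_cols}")
    Y = np.column_stack([df[f"y.{n}"].to_numpy(float) for n in names]) \
        if K else np.zeros((0, len(names)))
    u_cols = sorted((c for c in df.columns if c.startswith("u.")),
                    key=lambda c: int(c.split(".", 1)[1]))
    i_cols = sorted((c for c in df.columns if c.startswith("i.")),
                    key=lambda c: int(c.split(".", 1)[1]))
    U = df[u_cols].to_numpy(float).reshape(K, -1) if u_cols else None
    I = df[i_cols].to_numpy(float).reshape(K, -1) if i_cols else None
    status = np.full((K, len(names)), OBSERVED, dtype=int)
    thresholds = np.full((K, len(names)), np.nan)
    for j, n in enumerate(names):
        scol = f"status.{n}"
        if scol in df.columns and K:
            try:
                status[:, j] = [STATUS_CODES[s] for s in df[scol]]
            except KeyError as e:
                raise ValueError(f"{scol}: unknown status label {e}") from e
        tcol = f"threshold.{n}"
        if tcol in df.columns and K:
            thresholds[:, j] = df[tcol].to_numpy(float)
    return TrialSession(Y=Y, U=U, I=I, status=status, thresholds=thresholds)
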