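import numpy as np
import pytest

import cogstate as cs


@pytest.fixture
def scalar_bernoulli_spec():
    """Minimal well-formed 1-D model with a single binary channel."""
    state = cs.StateModel(A=[[0.99]], B=np.zeros((1, 0)), Q=[[1e-4]],
                          x0=[0.0], P0=[[1.0]])
    ch = cs.ObservationChannel("choice", "bernoulli", bias=0.0, C=[1.0])
    return cs.ModelSpec(state=state, channels=[ch])


@pytest.fixture
def gaussian_spec_2d():
    """2-D all-normal model for exact Kalman comparisons."""
    state = cs.StateModel(A=[[0.9, 0.1], [0.0, 0.8]], B=np.zeros((2, 1)),
                          Q=[[0.05, 0.01], [0.01, 0.08]],
                          x0=[0.3, -0.2], P0=np.eye(2) * 0.5)
    chs = [cs.ObservationChannel("y1", "normal", bias=0.1, C=[1.0, 0.5],
                                 dispersion=0.2),
           cs.ObservationChannel("y2", "normal", bias=-0.3, C=[0.2, 1.0],
                                 dispersion=0.3)]
    return cs.ModelSpec(state=state, channels=chs)


@pytest.fixture
def mixed_spec_1d():
    """1-D model with bernoulli + censorable lognormal channels."""
    state = cs.StateModel(A=[[0.9]], B=np.zeros((1, 0)), Q=[[0.03]],
                          x0=[0.0], P0=[[0.3]],
                          mask_A=[[True]], mask_Q=[[True]],
                          mask_x0=[False], mask_P0=[[False]])
    b = cs.ObservationChannel("choice", "bernoulli", bias=0.5, C=[1.0],
                              mask_C=[False])
    r = cs.ObservationChannel("rt", "lognormal", bias=-0.5, C=[1.2],
                              dispersion=0.03, censorable=True)
    return cs.ModelSpec(state=state, channels=[b, r])


def exact_kalman(session, spec):
    """Independent textbook Kalman filter + RTS smoother for normal channels.

    Used as the oracle against the package's Laplace recursion; written
    directly from the standard equations, sharing no code with it.
    """
    st = spec.state
    d, K = st.d, session.K
    C = np.array([c.C for c in spec.channels])
    bias = np.array([c.bias for c in spec.channels])
    R = np.diag([c.dispersion for c in spec.channels])
    xp = np.zeros((K, d)); Pp = np.zeros((K, d, d))
    xf = np.zeros((K, d)); Pf = np.zeros((K, d, d))
    ll = 0.0
    m, P = st.x0.copy(), st.P0.copy()
    for k in range(K):
        if k > 0:
            m = st.A @ xf[k - 1] + st.B @ session.U[k - 1]
            P = st.A @ Pf[k - 1] @ st.A.T + st.Q
        xp[k], Pp[k] = m, P
        obs = session.status[k] == cs.OBSERVED
        if obs.any():
            Co, Ro = C[obs], R[np.ix_(obs, obs)]
            y = session.Y[k, obs]
            S = Co @ P @ Co.T + Ro
            innov = y - Co @ m - bias[obs]
            Si = np.linalg.inv(S)
            ll += -0.5 * (len(y) * np.log(2 * np.pi) + np.linalg.slogdet(S)[1]
                          + innov @ Si @ innov)
            G = P @ Co.T @ Si
            m = m + G @ innov
            P = (np.eye(d) - G @ Co) @ P
        xf[k], Pf[k] = m, P
    xs = xf.copy(); Ps = Pf.copy()
    for k in range(K - 2, -1, -1):
        J = Pf[k] @ st.A.T @ np.linalg.inv(Pp[k + 1])
        xs[k] = xf[k] + J @ (xs[k + 1] - xp[k + 1])
        Ps[k] = Pf[k] + J @ (Ps[k + 1] - Pp[k + 1]) @ J.T
    return dict(x_pred=xp, P_pred=Pp, x_filt=xf, P_filt=Pf,
                x_smooth=xs, P_smooth=Ps, loglik=ll)
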