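"""E-step statistics, M-step updates, EM driver, and direct ML fitting."""

import warnings

import numpy as np
import pytest

import cogstate as cs
from cogstate._params import get_free_params, set_free_params
from cogstate.em import (EStepStats, e_step, m_step_obs, m_step_state,
                         marginal_loglik_and_score)


def _all_fixed(spec):
    out = spec.copy()
    st = out.state
    st.mask_A[:] = False
    st.mask_B[:] = False
    st.mask_Q[:] = False
    st.mask_x0[:] = False
    st.mask_P0[:] = False
    for ch in out.channels:
        ch.mask_bias = False
        ch.mask_C[:] = False
        ch.mask_D[:] = False
        ch.mask_dispersion = False
    return out


class TestEStep:
    def test_deterministic_state_pins_expectation(self):
        state = cs.StateModel(A=[[1.0]], B=np.zeros((1, 0)), Q=[[0.0]],
                              x0=[0.7], P0=[[0.0]])
        ch = cs.ObservationChannel("y", "normal", bias=0.0, C=[1.0],
                                   dispersion=0.5)
        spec = cs.ModelSpec(state=state, channels=[ch])
        sim = cs.simulate(spec, 10, seed=0)
        stats = e_step(sim.session, spec)
        np.testing.assert_allclose(stats.x_s[:, 0], 0.7, atol=1e-9)

    def test_all_missing_session_propagates_prior(self, gaussian_spec_2d):
        sim = cs.simulate(gaussian_spec_2d, 8, seed=1)
        sim.session.status[:, :] = cs.MISSING
        stats = e_step(sim.session, gaussian_spec_2d)
        st = gaussian_spec_2d.state
        m, P = st.x0.copy(), st.P0.copy()
        priors_m, priors_P = [m], [P]
        for _ in range(7):
            m = st.A @ m
            P = st.A @ P @ st.A.T + st.Q
            priors_m.append(m)
            priors_P.append(P)
        # no information anywhere: smoothing cannot improve on the prior
        np.testing.assert_allclose(stats.trajectory.x_filt, priors_m, atol=1e-10)
        np.testing.assert_allclose(stats.trajectory.P_filt, priors_P, atol=1e-10)

    def test_matches_joint_gaussian_oracle(self):
        """Smoothed moments equal one big multivariate-normal conditional."""
        K, d = 12, 1
        a, q, x0, p0 = 0.8, 0.3, 0.4, 0.6
        c, bias, r = 1.3, -0.2, 0.5
        state = cs.StateModel(A=[[a]], B=np.zeros((1, 0)), Q=[[q]],
                              x0=[x0], P0=[[p0]])
        ch = cs.ObservationChannel("y", "normal", bias=bias, C=[c], dispersion=r)
        spec = cs.ModelSpec(state=state, channels=[ch])
        sim = cs.simulate(spec, K, seed=3)
        y = sim.session.Y[:, 0]
        # joint prior covariance of x_1..x_K
        mx = np.array([x0 * a ** k for k in range(K)])
        var = np.empty(K)
        var[0] = p0
        for k in range(1, K):
            var[k] = a * a * var[k - 1] + q
        Sxx = np.empty((K, K))
        for i in range(K):
            for j in range(K):
                lo, hi = min(i, j), max(i, j)
                Sxx[i, j] = var[lo] * a ** (hi - lo)
        Syy = c * c * Sxx + np.eye(K) * r
        Sxy = c * Sxx
        my = c * mx + bias
        post_mean = mx + Sxy @ np.linalg.solve(Syy, y - my)
        post_cov = Sxx - Sxy @ np.linalg.solve(Syy, Sxy.T)
        stats = e_step(sim.session, spec)
        np.testing.assert_allclose(stats.x_s[:, 0], post_mean, atol=1e-8)
        np.testing.assert_allclose(stats.P_s[:, 0, 0], np.diag(post_cov),
                                   atol=1e-8)
        # lag-one covariances against the joint-Gaussian off-diagonal
        lag = np.array([stats.Exx1[k, 0, 0]
                        - stats.x_s[k, 0] * stats.x_s[k - 1, 0]
                        for k in range(1, K)])
        np.testing.assert_allclose(lag, np.diag(post_cov, -1), atol=1e-8)


class TestMStepState:
    def test_q_update_equals_mean_expected_squared_innovation(self):
        # 1-D, K=3, A and B fixed: hand-computed expected residual average
        a = 0.9
        x_s = np.array([[1.0], [2.0], [1.5]])
        P_s = np.array([[[0.2]], [[0.3]], [[0.1]]])
        P_lag = np.array([[[np.nan]], [[0.05]], [[0.04]]])
        Exx = P_s + np.einsum("ki,kj->kij", x_s, x_s)
        Exx1 = np.full((3, 1, 1), np.nan)
        for k in (1, 2):
            Exx1[k] = P_lag[k] + np.outer(x_s[k], x_s[k - 1])
        stats = EStepStats(x_s=x_s, P_s=P_s, Exx=Exx, Exx1=Exx1, loglik=0.0)
        # E[(x_k - a x_{k-1})^2] = Exx_k - 2a Exx1_k + a^2 Exx_{k-1}
        expected = np.mean([Exx[k, 0, 0] - 2 * a * Exx1[k, 0, 0]
                            + a * a * Exx[k - 1, 0, 0] for k in (1, 2)])
        state = cs.StateModel(A=[[a]], B=np.zeros((1, 0)), Q=[[1.0]],
                              x0=[0.0], P0=[[1.0]], mask_A=[[False]],
                              mask_Q=[[True]])
        session = cs.TrialSession(Y=np.zeros((3, 1)))
        new = m_step_state(stats, session, state)
        assert new.Q[0, 0] == pytest.approx(expected, abs=1e-12)
        assert new.A[0, 0] == a  # fixed entry untouched

    def test_fully_masked_state_returned_unchanged(self, gaussian_spec_2d):
        spec = _all_fixed(gaussian_spec_2d)
        sim = cs.simulate(spec, 15, seed=2)
        stats = e_step(sim.session, spec)
        new = m_step_state(stats, sim.session, spec.state)
        np.testing.assert_array_equal(new.A, spec.state.A)
        np.testing.assert_array_equal(new.Q, spec.state.Q)

    def test_ar_coefficient_and_noise_recovery(self):
        """Direct ML on a long AR(1)+noise session recovers (a, q)."""
        a, q = 0.95, 0.01
        state = cs.StateModel(A=[[a]], B=np.zeros((1, 0)), Q=[[q]],
                              x0=[0.0], P0=[[q / (1 - a * a)]],
                              mask_A=[[True]], mask_Q=[[True]],
                              mask_x0=[False], mask_P0=[[False]])
        ch = cs.ObservationChannel("y", "normal", bias=0.0, C=[1.0],
                                   dispersion=0.02, mask_bias=False,
                                   mask_C=[False], mask_dispersion=False)
        spec = cs.ModelSpec(state=state, channels=[ch])
        sim = cs.simulate(spec, 5000, seed=17)
        start = spec.copy()
        start.state.A[0, 0] = 0.8
        start.state.Q[0, 0] = 0.05
        res = cs.fit_ml(sim.session, start, anchor="off")
        fitted = dict(zip(res.param_labels, res.param_trace[-1]))
        assert abs(fitted["A[0,0]"] - a) < 0.02
        assert abs(fitted["Q[0,0]"] - q) < 0.2 * q


class TestMStepObs:
    def test_zero_state_loading_reduces_to_ols(self):
        """Normal channel with C pinned at 0: update is OLS on (Y, I)."""
        rng = np.random.default_rng(5)
        K = 200
        I = rng.normal(size=(K, 2))
        beta_true = np.array([0.7, -0.4, 1.1])  # bias, D1, D2
        y = beta_true[0] + I @ beta_true[1:] + rng.normal(0, 0.3, K)
        session = cs.TrialSession(Y=y[:, None], I=I)
        x_s = rng.normal(size=(K, 1))
        stats = EStepStats(x_s=x_s, P_s=np.full((K, 1, 1), 0.2),
                           Exx=np.zeros((K, 1, 1)), Exx1=np.zeros((K, 1, 1)),
                           loglik=0.0)
        ch = cs.ObservationChannel("y", "normal", bias=0.0, C=[0.0], D=[0.0, 0.0],
                                   dispersion=1.0, mask_C=[False])
        new = m_step_obs(stats, session, [ch])[0]
        Z = np.column_stack([np.ones(K), I])
        ols, *_ = np.linalg.lstsq(Z, y, rcond=None)
        assert new.bias == pytest.approx(ols[0], abs=1e-8)
        np.testing.assert_allclose(new.D, ols[1:], atol=1e-8)
        assert new.C[0] == 0.0

    def test_bernoulli_fit_on_true_states_recovers_coefficients(self):
        """Newton M-step with known states equals logistic-regression truth."""
        rng = np.random.default_rng(6)
        K = 5000
        x = rng.normal(0, 1, size=(K, 1))
        eta = 0.0 + 1.0 * x[:, 0]
        y = (rng.random(K) < 1 / (1 + np.exp(-eta))).astype(float)
        session = cs.TrialSession(Y=y[:, None])
        stats = EStepStats(x_s=x, P_s=np.zeros((K, 1, 1)),
                           Exx=np.zeros((K, 1, 1)), Exx1=np.zeros((K, 1, 1)),
                           loglik=0.0)
        ch = cs.ObservationChannel("b", "bernoulli", bias=0.3, C=[0.4])
        new = m_step_obs(stats, session, [ch])[0]
        assert abs(new.bias - 0.0) < 0.1
        assert abs(new.C[0] - 1.0) < 0.1

    def test_fixed_dispersion_only_loadings_move(self, mixed_spec_1d):
        spec = mixed_spec_1d.copy()
        spec.channels[1].mask_dispersion = False
        sim = cs.simulate(spec, 100, seed=7)
        stats = e_step(sim.session, spec)
        new = m_step_obs(stats, sim.session, spec.channels)[0:2]
        assert new[1].dispersion == spec.channels[1].dispersion
        assert new[1].bias != spec.channels[1].bias


class TestRunEM:
    def test_single_sweep_trace_lengths(self, mixed_spec_1d):
        sim = cs.simulate(mixed_spec_1d, 30, seed=1)
        res = cs.run_em(sim.session, mixed_spec_1d, max_iters=1, tol=0,
                        anchor="off")
        assert res.iterations == 1
        assert len(res.loglik_trace) == 2
        assert res.param_trace.shape[0] == 2

    def test_gaussian_em_loglik_nondecreasing(self, gaussian_spec_2d):
        spec = gaussian_spec_2d.copy()
        spec.state.mask_A[:] = False
        spec.state.mask_B[:] = False      # estimate Q and channel params only
        sim = cs.simulate(gaussian_spec_2d, 120, seed=4)
        start = spec.copy()
        start.state.Q = np.eye(2) * 0.2
        start.channels[0].bias = 0.0
        res = cs.run_em(sim.session, start, max_iters=25, tol=0, anchor="off")
        diffs = np.diff(res.loglik_trace)
        assert (diffs >= -1e-8).all()

    def test_masks_never_change_fixed_parameters(self, mixed_spec_1d):
        """Fuzz: fixed entries are bit-identical across all EM snapshots."""
        rng = np.random.default_rng(11)
        for trial in range(3):
            spec = mixed_spec_1d.copy()
            spec.state.mask_A = np.array([[bool(rng.random() < 0.5)]])
            spec.channels[1].mask_bias = bool(rng.random() < 0.5)
            spec.channels[1].mask_dispersion = bool(rng.random() < 0.5)
            fixed_before = {
                "A": (spec.state.A.copy(), spec.state.mask_A.copy()),
                "bias": (spec.channels[1].bias, spec.channels[1].mask_bias),
                "disp": (spec.channels[1].dispersion,
                         spec.channels[1].mask_dispersion),
            }
            sim = cs.simulate(mixed_spec_1d, 60, seed=100 + trial)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = cs.run_em(sim.session, spec, max_iters=5, tol=0,
                                anchor="off")
            if not fixed_before["A"][1][0, 0]:
                assert res.spec.state.A[0, 0] == fixed_before["A"][0][0, 0]
            if not fixed_before["bias"][1]:
                assert res.spec.channels[1].bias == fixed_before["bias"][0]
            if not fixed_before["disp"][1]:
                assert res.spec.channels[1].dispersion == fixed_before["disp"][0]

    def test_max_iters_must_be_positive(self, mixed_spec_1d):
        sim = cs.simulate(mixed_spec_1d, 10, seed=0)
        with pytest.raises(ValueError):
            cs.run_em(sim.session, mixed_spec_1d, max_iters=0)


class TestDirectML:
    def test_score_matches_finite_differences(self, mixed_spec_1d):
        sim = cs.simulate(mixed_spec_1d, 200, seed=13)
        ll, g = marginal_loglik_and_score(sim.session, mixed_spec_1d)
        labels, theta = get_free_params(mixed_spec_1d)
        h = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (cs.filter_pass(sim.session,
                                 set_free_params(mixed_spec_1d, tp)).loglik
                  - cs.filter_pass(sim.session,
                                   set_free_params(mixed_spec_1d, tm)).loglik) \
                / (2 * h)
            assert g[i] == pytest.approx(fd, rel=2e-3, abs=1e-4)

    def test_fit_ml_matches_closed_form_mle(self):
        """Bias-only normal model: ML fit equals the sample mean."""
        state = cs.StateModel(A=[[0.0]], B=np.zeros((1, 0)), Q=[[1e-12]],
                              x0=[0.0], P0=[[1e-12]], mask_A=[[False]],
                              mask_Q=[[False]])
        ch = cs.ObservationChannel("y", "normal", bias=0.0, C=[0.0],
                                   dispersion=0.5, mask_C=[False],
                                   mask_dispersion=False)
        spec = cs.ModelSpec(state=state, channels=[ch])
        rng = np.random.default_rng(0)
        y = rng.normal(1.4, np.sqrt(0.5), 300)
        session = cs.TrialSession(Y=y[:, None])
        res = cs.fit_ml(session, spec, anchor="off")
        assert res.spec.channels[0].bias == pytest.approx(y.mean(), abs=1e-5)
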