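"""Filter, smoother, and online-filter behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cogstate as cs
from cogstate import _families as fam
from cogstate.censoring import censored_eta_terms
from conftest import exact_kalman


class TestPredictStep:
    def test_identity_dynamics_leave_belief_unchanged(self):
        state = cs.StateModel(A=np.eye(2), B=np.zeros((2, 0)), Q=np.zeros((2, 2)),
                              x0=[0, 0], P0=np.eye(2))
        m, P = cs.predict_step([1.0, 2.0], np.eye(2) * 0.3, [], state)
        np.testing.assert_allclose(m, [1.0, 2.0])
        np.testing.assert_allclose(P, np.eye(2) * 0.3)

    def test_scalar_affine_mean(self):
        state = cs.StateModel(A=[[0.5]], B=[[1.0]], Q=[[0.0]], x0=[0], P0=[[1]])
        m, _ = cs.predict_step([2.0], [[0.1]], [3.0], state)
        assert m[0] == pytest.approx(4.0)

    def test_variance_addition(self):
        state = cs.StateModel(A=[[1.0]], B=np.zeros((1, 0)), Q=[[0.01]],
                              x0=[0], P0=[[1]])
        _, P = cs.predict_step([0.0], [[0.02]], [], state)
        assert P[0, 0] == pytest.approx(0.03)


class TestUpdateStep:
    def test_all_missing_returns_prediction_exactly(self, mixed_spec_1d):
        m, P, ll = cs.update_step([0.4], [[0.2]], [np.nan, np.nan],
                                  [cs.MISSING, cs.MISSING], [np.nan, np.nan],
                                  mixed_spec_1d.channels)
        assert m[0] == 0.4 and P[0, 0] == 0.2 and ll == 0.0

    def test_normal_channel_matches_conjugate_closed_form(self):
        ch = cs.ObservationChannel("y", "normal", bias=0.0, C=[1.0],
                                   dispersion=0.5)
        mu, v, y = 0.3, 0.8, 1.7
        m, P, ll = cs.update_step([mu], [[v]], [y], [cs.OBSERVED], [np.nan], [ch])
        gain = v / (v + 0.5)
        assert m[0] == pytest.approx(mu + gain * (y - mu), abs=1e-10)
        assert P[0, 0] == pytest.approx(v - gain * v, abs=1e-10)
        s = v + 0.5
        assert ll == pytest.approx(-0.5 * (np.log(2 * np.pi * s)
                                           + (y - mu) ** 2 / s), abs=1e-10)

    def test_bernoulli_evidence_moves_mean_monotonically(self):
        ch = cs.ObservationChannel("b", "bernoulli", bias=0.0, C=[1.0])
        up, _, _ = cs.update_step([0.0], [[1.0]], [1.0], [cs.OBSERVED],
                                  [np.nan], [ch])
        dn, _, _ = cs.update_step([0.0], [[1.0]], [0.0], [cs.OBSERVED],
                                  [np.nan], [ch])
        assert up[0] > 0.0 > dn[0]

    @pytest.mark.parametrize("kind", ["bernoulli", "gamma", "lognormal",
                                      "cens-lognormal"])
    def test_1d_update_matches_grid_integration(self, kind):
        """Posterior moments agree with brute-force numerical integration."""
        rng = np.random.default_rng(hash(kind) % 2**31)
        for _ in range(10):
            mu = rng.normal(0, 1)
            var = rng.uniform(0.005, 0.15)
            bias = rng.normal(0, 0.5)
            c = rng.uniform(0.3, 2.0)
            grid = np.linspace(mu - 8 * math.sqrt(var), mu + 8 * math.sqrt(var),
                               4001)
            eta = bias + c * grid
            if kind == "bernoulli":
                y, disp = float(rng.random() < 0.5), None
                ll = fam.loglik("bernoulli", y, eta, None)
                ch = cs.ObservationChannel("b", "bernoulli", bias=bias, C=[c])
                yv, flag, thr = y, cs.OBSERVED, np.nan
            elif kind == "cens-lognormal":
                disp = rng.uniform(0.01, 0.2)
                # keep the threshold within a few predictive SDs of the median
                thr = math.exp(bias + c * mu + rng.normal(0, 1.5)
                               * math.sqrt(disp + c * c * var))
                ll = censored_eta_terms("lognormal", thr, eta, disp)[0]
                ch = cs.ObservationChannel("r", "lognormal", bias=bias, C=[c],
                                           dispersion=disp, censorable=True)
                yv, flag = np.nan, cs.CENSORED
            else:
                disp = rng.uniform(2, 8) if kind == "gamma" else rng.uniform(0.01, 0.2)
                y = float(fam.sample(kind, np.array(bias + c * mu), disp, rng))
                ll = fam.loglik(kind, y, eta, disp)
                ch = cs.ObservationChannel("g", kind, bias=bias, C=[c],
                                           dispersion=disp)
                yv, flag, thr = y, cs.OBSERVED, np.nan
            logpost = -0.5 * (grid - mu) ** 2 / var + ll
            w = np.exp(logpost - logpost.max())
            w /= w.sum()
            tm = float(w @ grid)
            tv = float(w @ (grid - tm) ** 2)
            m, P, _ = cs.update_step([mu], [[var]], [yv], [flag], [thr], [ch])
            assert abs(m[0] - tm) <= 1e-3 * max(1, abs(tm))
            assert abs(P[0, 0] - tv) <= 1e-3 * max(1, abs(tv))


class TestFilterSmoother:
    def test_empty_session(self, gaussian_spec_2d):
        session = cs.TrialSession(Y=np.zeros((0, 2)))
        traj = cs.filter_pass(session, gaussian_spec_2d)
        assert traj.K == 0 and traj.loglik == 0.0
        traj = cs.smoother_pass(traj, gaussian_spec_2d)
        assert traj.x_smooth.shape == (0, 2)

    def test_gaussian_model_matches_exact_kalman(self, gaussian_spec_2d):
        sim = cs.simulate(gaussian_spec_2d, 50, seed=42)
        traj = cs.smoother_pass(cs.filter_pass(sim.session, gaussian_spec_2d),
                                gaussian_spec_2d)
        oracle = exact_kalman(sim.session, gaussian_spec_2d)
        for key in ("x_filt", "P_filt", "x_smooth", "P_smooth"):
            np.testing.assert_allclose(getattr(traj, key), oracle[key],
                                       atol=1e-8)
        assert traj.loglik == pytest.approx(oracle["loglik"], abs=1e-8)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(1, 3), st.integers(10, 100), st.integers(0, 10**6))
    def test_kalman_equivalence_randomized(self, d, K, seed):
        """Random all-normal models: filter/smoother equal exact recursions."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(d, d)) * 0.4
        state = cs.StateModel(A=A, B=np.zeros((d, 0)),
                              Q=np.diag(rng.uniform(0.01, 0.5, d)),
                              x0=rng.normal(size=d),
                              P0=np.diag(rng.uniform(0.1, 1.0, d)))
        chs = [cs.ObservationChannel(f"y{j}", "normal", bias=float(rng.normal()),
                                     C=rng.normal(size=d),
                                     dispersion=float(rng.uniform(0.05, 1)))
               for j in range(int(rng.integers(1, 3)))]
        spec = cs.ModelSpec(state=state, channels=chs)
        sim = cs.simulate(spec, K, seed=seed + 1)
        # sprinkle missing observations
        sim.session.status[rng.random((K, len(chs))) < 0.15] = cs.MISSING
        traj = cs.smoother_pass(cs.filter_pass(sim.session, spec), spec)
        oracle = exact_kalman(sim.session, spec)
        np.testing.assert_allclose(traj.x_smooth, oracle["x_smooth"], atol=1e-8)
        np.testing.assert_allclose(traj.P_smooth, oracle["P_smooth"], atol=1e-8)
        assert traj.loglik == pytest.approx(oracle["loglik"], abs=1e-8)

    def test_missing_trials_filtered_equals_predicted(self, mixed_spec_1d):
        sim = cs.simulate(mixed_spec_1d, 20, seed=1)
        sim.session.status[:, :] = cs.MISSING
        traj = cs.filter_pass(sim.session, mixed_spec_1d)
        np.testing.assert_array_equal(traj.x_filt, traj.x_pred)
        np.testing.assert_array_equal(traj.P_filt, traj.P_pred)
        assert traj.loglik == 0.0

    def test_smoothed_equals_filtered_at_last_trial(self, mixed_spec_1d):
        sim = cs.simulate(mixed_spec_1d, 30, seed=5)
        traj = cs.smoother_pass(cs.filter_pass(sim.session, mixed_spec_1d),
                                mixed_spec_1d)
        np.testing.assert_array_equal(traj.x_smooth[-1], traj.x_filt[-1])
        np.testing.assert_array_equal(traj.P_smooth[-1], traj.P_filt[-1])

    def test_degenerate_random_walk_smooths_to_constant(self):
        state = cs.StateModel(A=[[1.0]], B=np.zeros((1, 0)), Q=[[0.0]],
                              x0=[0.0], P0=[[1.0]])
        ch = cs.ObservationChannel("y", "normal", bias=0.0, C=[1.0],
                                   dispersion=0.5)
        spec = cs.ModelSpec(state=state, channels=[ch])
        sim = cs.simulate(spec, 25, seed=0)
        traj = cs.smoother_pass(cs.filter_pass(sim.session, spec), spec)
        assert np.ptp(traj.x_smooth[:, 0]) < 1e-9

    def test_smoothing_reduces_uncertainty(self, mixed_spec_1d):
        sim = cs.simulate(mixed_spec_1d, 60, seed=9)
        traj = cs.smoother_pass(cs.filter_pass(sim.session, mixed_spec_1d),
                                mixed_spec_1d)
        tr_f = np.trace(traj.P_filt, axis1=1, axis2=2)
        tr_s = np.trace(traj.P_smooth, axis1=1, axis2=2)
        assert (tr_s <= tr_f + 1e-10).all()


class TestOnlineFilter:
    def test_streaming_equals_batch_bit_for_bit(self):
        sim = cs.make_censored_rt_experiment(seed=3)
        from cogstate.simulators import censored_rt_estimation_spec
        spec = censored_rt_estimation_spec()
        batch = cs.filter_pass(sim.session, spec,
                               cs.CensoringMethod("full_likelihood"))
        of = cs.OnlineFilter(spec, cs.CensoringMethod("full_likelihood"))
        for k, (y, u, i, s, t) in enumerate(sim.session.rows()):
            m, P = of.step(y, u, i, s, t)
            np.testing.assert_array_equal(m, batch.x_filt[k])
            np.testing.assert_array_equal(P, batch.P_filt[k])
        # summation order differs between streaming and the batch array sum
        assert of.loglik == pytest.approx(batch.loglik, abs=1e-10)

    def test_all_missing_stream_grows_variance(self):
        # random walk: pure prediction accumulates process noise every trial
        state = cs.StateModel(A=[[1.0]], B=np.zeros((1, 0)), Q=[[0.02]],
                              x0=[0.0], P0=[[0.1]])
        spec = cs.ModelSpec(state=state, channels=[cs.ObservationChannel(
            "y", "normal", bias=0.0, C=[1.0], dispersion=0.5)])
        of = cs.OnlineFilter(spec)
        traces = []
        for _ in range(15):
            _, P = of.step([np.nan], [], [], [cs.MISSING], [np.nan])
            traces.append(np.trace(P))
        assert all(b >= a - 1e-12 for a, b in zip(traces, traces[1:]))

    def test_mid_stream_refit_matches_restart(self, mixed_spec_1d):
        """Swapping the spec mid-stream equals restarting from the belief."""
        sim = cs.simulate(mixed_spec_1d, 40, seed=8)
        spec2 = mixed_spec_1d.copy()
        spec2.state.Q[0, 0] = 0.08
        spec2.channels[1].bias = -0.3
        rows = list(sim.session.rows())
        a = cs.OnlineFilter(mixed_spec_1d)
        for r in rows[:20]:
            a.step(*r)
        a.update_spec(spec2)
        out_a = [a.step(*r) for r in rows[20:]]
        b = cs.OnlineFilter(mixed_spec_1d)
        for r in rows[:20]:
            b.step(*r)
        b2 = cs.OnlineFilter(spec2)
        b2._mean, b2._cov = b._mean, b._cov
        b2._prev_u, b2._k = b._prev_u, b._k
        out_b = [b2.step(*r) for r in rows[20:]]
        for (ma, Pa), (mb, Pb) in zip(out_a, out_b):
            np.testing.assert_array_equal(ma, mb)
            np.testing.assert_array_equal(Pa, Pb)


def test_trajectory_frame_shape(mixed_spec_1d):
    sim = cs.simulate(mixed_spec_1d, 12, seed=2)
    traj = cs.smoother_pass(cs.filter_pass(sim.session, mixed_spec_1d),
                            mixed_spec_1d)
    df = cs.trajectory_frame(traj, mixed_spec_1d)
    assert list(df["trial"]) == list(range(1, 13))
    for col in ("x_pred.0", "x_filt.0", "x_smooth.0", "var_filt.0.0", "loglik"):
        assert col in df.columns
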