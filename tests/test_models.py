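"""Within-trial control equations and between-trial learning rules."""

import numpy as np
import pytest

import reachadapt as ra
from reachadapt.design import TrialSchedule, TrialSpec, UncertaintyLevel
from reachadapt.models import (ContractViolation, ModelParams, ModelSpec,
                               SessionState, aim_output, feedback_command,
                               feedforward_output, endpoint_error,
                               midpoint_error, predict_session,
                               predict_session_reference, schedule_arrays,
                               simulate_session, simulate_trial,
                               update_fast_state, update_feedback_gain,
                               update_slow_state)

L, M, H, INF = UncertaintyLevel


def _mini_schedule(rotations, mp_levels, ep_levels=None, phase="adaptation"):
    ep_levels = ep_levels or [None] * len(rotations)
    trials = tuple(
        TrialSpec(i + 1, phase, r if phase == "adaptation" else 0.0, mp, ep)
        for i, (r, mp, ep) in enumerate(zip(rotations, mp_levels, ep_levels)))
    return TrialSchedule(0, trials, seed=-1)


class TestElementaryOps:
    def test_feedforward_output_sums_states_per_spec(self):
        two = ModelSpec("error_scaling", 2)
        one = ModelSpec("error_scaling", 1)
        assert feedforward_output(SessionState(0, 0, 0.3), two) == 0
        assert feedforward_output(SessionState(3, 4, 0.3), two) == 7
        assert feedforward_output(SessionState(3, 4, 0.3), one) == 3

    def test_midpoint_and_endpoint_errors(self):
        assert midpoint_error(0, 12) == 12
        assert midpoint_error(-12, 12) == 0
        assert midpoint_error(-5, 12) == 7
        assert endpoint_error(-7, 12) == 5

    def test_feedback_command(self):
        eta = (0.5, 0.5, 0.5, 0.5)
        assert feedback_command(1.0, 10.0, eta, L) == -5.0
        assert feedback_command(1.0, 0.0, eta, M) == 0.0
        assert feedback_command(1.0, 10.0, eta, None) == 0.0

    def test_feedback_gain_update(self):
        p = ModelParams(beta_fb=1.0, alpha_fb=0.3)
        assert update_feedback_gain(1.0, 0.0, p) == 1.0
        p = ModelParams(beta_fb=0.8, alpha_fb=0.1)
        assert update_feedback_gain(0.5, 10.0, p) == pytest.approx(1.4)
        p = ModelParams(beta_fb=0.0, alpha_fb=0.0)
        assert update_feedback_gain(7.0, 3.0, p) == 0.0

    def test_slow_state_update(self):
        spec = ModelSpec("error_scaling", 2)
        p = ModelParams(alpha_s=0.3, beta_s=0.99, lambda_s=0.0)
        assert update_slow_state(0, 0, 0, 0, p, spec) == 0
        assert update_slow_state(10, 0, 0, 0, p, spec) == pytest.approx(9.9)
        p = ModelParams(alpha_s=0.05, beta_s=1.0, lambda_s=0.0)
        # d_MP = 12 plus the midpoint-command error term (0 - (-12))
        assert update_slow_state(0, 12, 0, -12, p, spec) == pytest.approx(1.2)
        with pytest.raises(ContractViolation):
            update_slow_state(0, 0, 0, 0, p, ModelSpec("error_scaling", 1))

    def test_fast_state_family_dispatch(self):
        p = ModelParams(alpha_f=0.2, beta_f=1.0, lambda_f=0.0, gamma=1.0,
                        nu_ff=(0.5, 0.5, 0.5, 0.5))
        spec = ModelSpec("error_scaling", 1)
        assert update_fast_state(0, 10, 0, 0, L, None, p, spec) == pytest.approx(1.0)

        p = ModelParams(lambda_f=5.0, gamma=1.0, nu_ff=(0.6, 0.6, 0.6, 0.6))
        spec = ModelSpec("state_aim_scaling", 2)
        for x in (0.0, 3.0, -8.0):
            for d in (0.0, 12.0):
                assert update_fast_state(x, d, d, 0, L, H, p, spec) == pytest.approx(3.0)

    def test_bias_scaling_identity_reduces_to_unscaled(self):
        p = ModelParams(alpha_f=0.1, beta_f=0.9, lambda_f=2.0, gamma=0.3,
                        nu_ff=(1.0, 1.0, 1.0, 1.0))
        spec = ModelSpec("bias_scaling", 1)
        got = update_fast_state(4.0, 3.0, 1.0, -0.5, M, H, p, spec)
        expected = 0.9 * 4.0 + 0.1 * 3.0 + 0.1 * (1.0 - (-0.5)) + 2.0
        assert got == pytest.approx(expected)

    def test_aim_output_contract(self):
        p = ModelParams(lambda_f=4.0, gamma=0.5, nu_ff=(1.0, 0.0, 0.0, 0.0))
        spec = ModelSpec("output_aim_scaling", 2)
        assert aim_output(L, M, p, spec) == pytest.approx(2.0)
        p0 = ModelParams(lambda_f=9.0, gamma=1.0, nu_ff=(0.0, 0.0, 0.0, 0.0))
        assert aim_output(L, L, p0, spec) == 0.0
        with pytest.raises(ContractViolation):
            aim_output(L, L, p, ModelSpec("error_scaling", 2))

    def test_aim_constant_scaling_gives_flat_aim(self):
        p = ModelParams(lambda_f=4.0, gamma=0.3, nu_ff=(0.5, 0.5, 0.5, 0.5))
        spec = ModelSpec("output_aim_scaling", 2)
        vals = [aim_output(a, b, p, spec)
                for a in UncertaintyLevel for b in UncertaintyLevel]
        np.testing.assert_allclose(vals, 2.0)


class TestSimulateTrial:
    def test_inert_learner_passes_rotation_through(self):
        trial = TrialSpec(1, "adaptation", 12.0, L, None)
        state, out = simulate_trial(SessionState(), trial, None,
                                    ModelParams(nu_ff=(0,) * 4, nu_fb=(0,) * 4),
                                    ModelSpec("error_scaling", 1))
        assert (out.y_t0, out.delta_MP, out.y_fb_MP, out.y_tMP,
                out.delta_EP) == (0, 12, 0, 0, 12)
        assert (state.x_fast, state.x_slow, state.x_fb) == (0, 0, 0)

    def test_full_gain_feedback_cancels_endpoint_error(self):
        trial = TrialSpec(1, "adaptation", 12.0, L, None)
        params = ModelParams(x_fb_init=1.0, nu_fb=(1.0,) * 4, nu_ff=(0,) * 4)
        _, out = simulate_trial(SessionState(x_fb=1.0), trial, None, params,
                                ModelSpec("error_scaling", 1))
        assert out.y_fb_MP == -12
        assert out.y_tMP == -12
        assert out.delta_EP == 0

    def test_feedback_never_contributes_at_t0(self, exp1_schedule):
        """y_fb(n, t0) = 0: the plan is independent of the feedback gain."""
        import dataclasses
        spec = ModelSpec("error_scaling", 2)
        base = ra.synth.default_generator_params("error_scaling")
        out_a = simulate_session(exp1_schedule, base, spec)
        # first-trial plan must ignore x_fb_init and eta entirely
        big = dataclasses.replace(base, x_fb_init=2.0, nu_fb=(1.0,) * 4)
        out_b = simulate_session(exp1_schedule, big, spec)
        assert out_a[0].y_t0 == out_b[0].y_t0


class TestSessionDynamics:
    def test_five_trial_hand_unrolled_trace(self):
        """Straight-line arithmetic from the control equations matches the
        simulator to machine precision."""
        rot = [10.0, 12.0, 14.0, 8.0, 11.0]
        lv = [L, M, H, INF, L]
        sched = _mini_schedule(rot, lv)
        a, b, lam = 0.2, 0.9, 0.5
        nu = (1.0, 0.7, 0.4, 0.2)
        eta = (0.6, 0.4, 0.2, 0.0)
        afb, bfb, xfb0, g = 0.1, 0.8, 0.5, 0.7
        params = ModelParams(alpha_f=a, beta_f=b, lambda_f=lam,
                             alpha_fb=afb, beta_fb=bfb, x_fb_init=xfb0,
                             nu_ff=nu, nu_fb=eta, gamma=g)
        spec = ModelSpec("error_scaling", 1)

        x, xfb = 0.0, xfb0
        expected = []
        for r, mp in zip(rot, lv):
            y0 = x
            dmp = y0 + r
            yfb = -xfb * dmp * eta[int(mp)]
            ymp = y0 + yfb
            dep = ymp + r
            expected.append((y0, ymp, dmp, dep, yfb))
            x = b * x + g * nu[int(mp)] * a * dmp \
                + (1 - g) * nu[3] * a * (dep - yfb) + lam
            xfb = bfb * xfb + afb * dep

        outs = simulate_session(sched, params, spec)
        for out, (y0, ymp, dmp, dep, yfb) in zip(outs, expected):
            assert out.y_t0 == pytest.approx(y0, abs=1e-12)
            assert out.y_tMP == pytest.approx(ymp, abs=1e-12)
            assert out.delta_MP == pytest.approx(dmp, abs=1e-12)
            assert out.delta_EP == pytest.approx(dep, abs=1e-12)
            assert out.y_fb_MP == pytest.approx(yfb, abs=1e-12)
            assert out.y_tEP == out.y_tMP

    def test_identity_scaling_collapses_state_families(self, exp1_schedule):
        """With nu = eta = 1 every state-scaling family reduces to the
        unscaled single-error state-space dynamics.

        Because the endpoint learning signal satisfies d_EP - y_fb = d_MP
        identically, the base update is x <- b*x + a_eff*d_MP + l with
        a_eff = a for error-scaling (the gamma weights sum to one) and
        a_eff = 2a for retention- and bias-scaling (both error terms enter
        unweighted).  The oracle is that unscaled recursion, written
        independently below.
        """
        def oracle(a_f_eff, a_s_eff, arrays):
            xf = xs = 0.0
            xfb = 0.4
            traj = []
            for n in range(len(arrays["r"])):
                y0 = xf + xs
                dmp = y0 + float(arrays["r"][n])
                adapt = bool(arrays["adapt"][n])
                yfb = -xfb * dmp if adapt else 0.0
                traj.append(y0 + yfb)
                e = dmp if adapt else 0.0
                xf = 0.8 * xf + a_f_eff * e + 0.4
                xs = 0.95 * xs + a_s_eff * e
                xfb = 0.7 * xfb + 0.02 * ((y0 + yfb + float(arrays["r"][n]))
                                          if adapt else 0.0)
            return np.array(traj)

        params = ModelParams(alpha_f=0.05, beta_f=0.8, lambda_f=0.4,
                             alpha_s=0.005, beta_s=0.95, lambda_s=0.0,
                             alpha_fb=0.02, beta_fb=0.7, x_fb_init=0.4,
                             nu_ff=(1.0,) * 4, nu_fb=(1.0,) * 4, gamma=0.35)
        arrays = schedule_arrays(exp1_schedule)
        expected = {"error_scaling": oracle(0.05, 0.01, arrays),
                    "retention_scaling": oracle(0.10, 0.01, arrays),
                    "bias_scaling": oracle(0.10, 0.01, arrays)}
        for family, want in expected.items():
            outs = simulate_session(exp1_schedule, params, ModelSpec(family, 2))
            ymp = np.array([o.y_tMP for o in outs])
            np.testing.assert_allclose(ymp, want, rtol=0, atol=1e-9)

    def test_slow_state_invariant_to_uncertainty_permutation(self):
        """With an inert fast state and no feedback, permuting the
        uncertainty labels leaves the slow-state trajectory unchanged."""
        rot = list(np.linspace(8, 16, 30))
        sched_a = _mini_schedule(rot, [L, M, H, INF] * 7 + [L, M])
        sched_b = _mini_schedule(rot, [INF, H, M, L] * 7 + [H, INF])
        params = ModelParams(alpha_f=0.0, beta_f=0.0, lambda_f=0.0,
                             alpha_s=0.05, beta_s=0.95,
                             nu_ff=(1.0, 0.5, 0.2, 0.0), nu_fb=(0.0,) * 4)
        spec = ModelSpec("error_scaling", 2)
        ya = [o.y_tMP for o in simulate_session(sched_a, params, spec)]
        yb = [o.y_tMP for o in simulate_session(sched_b, params, spec)]
        np.testing.assert_allclose(ya, yb, atol=1e-12)

    def test_washout_geometric_decay(self):
        sched = _mini_schedule([0.0] * 40, [None] * 40, phase="washout")
        params = ModelParams(alpha_f=0.3, beta_f=0.9, lambda_f=0.0,
                             nu_ff=(1.0,) * 4, nu_fb=(1.0,) * 4)
        spec = ModelSpec("error_scaling", 1)
        outs = simulate_session(sched, params, spec,
                                initial_state=SessionState(5.0, 0.0, 0.0))
        y0 = np.array([o.y_t0 for o in outs])
        np.testing.assert_allclose(y0, 5.0 * 0.9 ** np.arange(40), rtol=1e-12)
        assert all(o.y_fb_MP == 0 for o in outs)

    def test_state_aim_next_state_depends_only_on_levels(self):
        """Brute force over all 4x4 level pairs: the fast state after trial n
        is a function of (trial n levels, gamma, nu, lambda) alone."""
        params = ModelParams(lambda_f=0.8, gamma=0.3,
                             nu_ff=(0.9, 0.6, 0.3, 0.1), nu_fb=(0.5,) * 4,
                             alpha_s=0.0, beta_s=0.0)
        spec = ModelSpec("state_aim_scaling", 2)
        for mp in UncertaintyLevel:
            for ep in UncertaintyLevel:
                expected = (0.3 * params.nu_ff[mp]
                            + 0.7 * params.nu_ff[ep]) * 0.8
                for x0 in (0.0, 4.0):
                    for r in (0.0, 15.0):
                        trial = TrialSpec(1, "adaptation", r, mp, ep)
                        state, _ = simulate_trial(SessionState(x0, 0, 1.0),
                                                  trial, None, params, spec)
                        assert state.x_fast == pytest.approx(expected)

    def test_output_aim_equals_state_aim_after_first_trial(self, exp1_schedule):
        params = ra.synth.default_generator_params("state_aim_scaling")
        ya = [o.y_tMP for o in simulate_session(
            exp1_schedule, params, ModelSpec("state_aim_scaling", 2))]
        yb = [o.y_tMP for o in simulate_session(
            exp1_schedule, params, ModelSpec("output_aim_scaling", 2))]
        np.testing.assert_allclose(ya[1:], yb[1:], atol=1e-10)

    def test_session_is_deterministic_and_length_preserving(self, exp1_schedule):
        params = ra.synth.default_generator_params("bias_scaling")
        spec = ModelSpec("bias_scaling", 2)
        a = simulate_session(exp1_schedule, params, spec)
        b = simulate_session(exp1_schedule, params, spec)
        assert len(a) == len(exp1_schedule)
        assert all(x == y for x, y in zip(a, b))

    def test_stability_inside_bounds(self, exp1_schedule):
        """Contractive parameter grids stay finite over a full session."""
        spec = ModelSpec("error_scaling", 2)
        for beta in (0.5, 0.9, 1.0):
            for alpha in (0.05, 0.2):
                p = ModelParams(alpha_f=alpha, beta_f=beta * 0.9,
                                lambda_f=1.0, alpha_s=0.01, beta_s=0.9,
                                alpha_fb=0.05, beta_fb=0.8, x_fb_init=0.5,
                                nu_ff=(1.0, 0.5, 0.2, 0.0),
                                nu_fb=(1.0, 0.5, 0.2, 0.0), gamma=0.5)
                outs = simulate_session(exp1_schedule, p, spec)
                assert np.isfinite([o.y_tMP for o in outs]).all()


class TestEngines:
    def test_vectorized_engine_matches_scalar_fold(self, exp1_schedule):
        arrays = schedule_arrays(exp1_schedule)
        rng = np.random.default_rng(5)
        for family in ("error_scaling", "state_aim_scaling",
                       "output_aim_scaling"):
            spec = ModelSpec(family, 2)
            params = ra.synth.default_generator_params(family)
            noise = rng.normal(0, 1, len(exp1_schedule))
            outs = simulate_session(exp1_schedule, params, spec,
                                    motor_noise=noise)
            vec = predict_session(arrays, spec, params.to_vector()[None, :],
                                  motor_noise=noise)
            np.testing.assert_allclose([o.y_tMP for o in outs],
                                       vec["y_tMP"][0], atol=1e-10)
            np.testing.assert_allclose([o.y_t0 for o in outs],
                                       vec["y_t0"][0], atol=1e-10)

    def test_jitted_kernel_matches_reference_path(self, exp1_schedule):
        arrays = schedule_arrays(exp1_schedule)
        rng = np.random.default_rng(8)
        theta = rng.uniform(-0.5, 1.0, size=(12, 18))
        for family in ("retention_scaling", "bias_scaling"):
            spec = ModelSpec(family, 2)
            fast = predict_session(arrays, spec, theta)
            ref = predict_session_reference(arrays, spec, theta)
            np.testing.assert_array_equal(fast["y_tMP"], ref["y_tMP"])
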