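"""Mean-field (Wilson-Cowan) model: transfer function, dynamics, learning."""

import numpy as np
import pytest
import sympy

from banetsim.rate import (
    RateModelState,
    RateParams,
    RatePhase,
    RateStimulus,
    default_rate_protocol,
    rate_trial_summary,
    run_rate_phase,
    run_rate_protocol,
    sigmoid_transfer,
    step_rate_dynamics,
    update_rate_weights,
)


class TestSigmoid:
    def test_midpoint_is_half(self):
        assert sigmoid_transfer(1.2, p=5.0, theta=1.2) == pytest.approx(0.5)

    def test_saturation(self):
        assert sigmoid_transfer(1e3, p=1.0, theta=0.0) == pytest.approx(1.0)
        assert sigmoid_transfer(-1e3, p=1.0, theta=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_high_precision_logistic(self):
        # independent arbitrary-precision evaluation of 1/(1+exp(-p(x-theta)))
        expected = float(1 / (1 + sympy.exp(-sympy.Integer(2))).evalf(50))
        assert sigmoid_transfer(2.0, p=1.0, theta=0.0) == pytest.approx(expected, rel=1e-14)

    def test_strictly_increasing_and_bounded(self):
        x = np.linspace(-10, 10, 201)
        y = sigmoid_transfer(x, p=3.0, theta=0.5)
        assert np.all(np.diff(y) > 0)
        assert np.all((y > 0) & (y < 1))

    def test_max_slope_at_theta(self):
        x = np.linspace(-5, 5, 2001)
        y = sigmoid_transfer(x, p=2.0, theta=1.0)
        slope = np.gradient(y, x)
        assert x[np.argmax(slope)] == pytest.approx(1.0, abs=0.02)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            sigmoid_transfer(np.nan, p=1.0, theta=0.0)
        with pytest.raises(ValueError):
            sigmoid_transfer(0.0, p=0.0, theta=0.0)


class TestDynamics:
    def test_zero_input_zero_activity_near_fixed_point(self):
        # with no input the sigmoid leaks a tiny S(-theta) drive; with a hard
        # zero transfer output the origin is a fixed point of the leak
        params = RateParams(noise_sigma=0.0, sigmoid_theta=50.0, sigmoid_p=1.0)
        state = RateModelState(act_A=0.0, act_B=0.0)
        stim = RateStimulus(cs_times_ms=(), context=None)
        for _ in range(100):
            state = step_rate_dynamics(state, params, stim, dt_ms=0.1)
        assert state.act_A == pytest.approx(0.0, abs=1e-12)
        assert state.act_B == pytest.approx(0.0, abs=1e-12)

    def test_matches_fine_step_reference(self):
        # deterministic-limit oracle: the same ODE integrated at dt/100
        params = RateParams(noise_sigma=0.0)
        stim = RateStimulus(cs_times_ms=(0.0,), cs_duration_ms=1e6, context="A")

        def integrate(dt, t_end):
            state = RateModelState(act_A=0.1, act_B=0.05, w_A_CS=0.3, w_B_CS=0.1)
            while state.t_ms < t_end - 1e-9:
                state = step_rate_dynamics(state, params, stim, dt)
            return state

        coarse = integrate(0.1, 100.0)
        fine = integrate(0.001, 100.0)
        assert coarse.act_A == pytest.approx(fine.act_A, rel=1e-3)
        assert coarse.act_B == pytest.approx(fine.act_B, rel=1e-3)

    def test_dt_guard(self):
        params = RateParams()
        with pytest.raises(ValueError):
            step_rate_dynamics(RateModelState(), params, RateStimulus(), dt_ms=params.tau_A_ms)

    def test_cs_pulse_excites_a_and_inhibits_b(self):
        # with potentiated CS weights onto A, a pulse raises A and pushes B
        # below its pre-pulse level through the mutual inhibition
        params = RateParams(noise_sigma=0.0)
        stim = RateStimulus(cs_times_ms=(50.0,), cs_duration_ms=50.0, context="A")
        state = RateModelState(act_A=0.02, act_B=0.02, w_A_CS=0.4, w_A_CTX=0.4)
        trace_a, trace_b = [], []
        for _ in range(1500):
            state = step_rate_dynamics(state, params, stim, 0.1)
            trace_a.append(state.act_A)
            trace_b.append(state.act_B)
        trace_a, trace_b = np.array(trace_a), np.array(trace_b)
        during = slice(500, 1000)
        assert trace_a[during].max() > 5 * trace_a[:500].max()
        assert trace_b[during].min() < trace_b[499]


class TestWeights:
    def test_coincidence_required(self):
        params = RateParams()
        s0 = RateModelState()
        s1 = update_rate_weights(s0, params, cs_active=True, ctx_on="A")
        assert s1.w_A_CS == pytest.approx(s0.w_A_CS + params.a_A)
        assert s1.w_A_CTX == pytest.approx(s0.w_A_CTX + params.a_A)
        assert s1.w_B_CS == s0.w_B_CS
        s2 = update_rate_weights(s0, params, cs_active=True, ctx_on=None)
        assert (s2.w_A_CS, s2.w_B_CS) == (s0.w_A_CS, s0.w_B_CS)
        s3 = update_rate_weights(s0, params, cs_active=False, ctx_on="A")
        assert s3.w_A_CS == s0.w_A_CS

    def test_extinction_staircase_monotone_no_depotentiation(self):
        df = run_rate_protocol(RateParams(noise_sigma=0.0), n_repeats=1, seed=0)
        ext = df[df.phase == "extinction"]
        w_b = ext.w_B_CS.to_numpy()
        assert np.all(np.diff(w_b) >= 0) and w_b[-1] > w_b[0]
        # population-A CS weight untouched during extinction
        assert ext.w_A_CS.nunique() == 1
        # no plastic weight ever decreases anywhere in the protocol
        for col in ("w_A_CS", "w_B_CS", "w_A_CTX", "w_B_CTX"):
            assert np.all(np.diff(df[df.repeat == 0][col].to_numpy()) >= 0)


class TestProtocol:
    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            run_rate_protocol(RateParams(), phases=[], n_repeats=1)

    def test_conditioning_increases_a_then_extinction_flips_dominance(self):
        summary = rate_trial_summary(RateParams(), n_repeats=10, seed=1)
        cond = summary[summary.phase == "conditioning"]
        ext = summary[summary.phase == "extinction"]
        assert np.all(np.diff(cond.peak_A.to_numpy()) > 0)
        assert cond.peak_A.iloc[-1] > 5 * cond.peak_A.iloc[0]
        # during extinction, B's response grows and ends dominant, suppressing A
        assert np.all(np.diff(ext.peak_B.to_numpy()) > 0)
        assert ext.peak_B.iloc[-1] > 2 * ext.peak_A.iloc[-1]
        assert ext.peak_A.iloc[-1] < 0.5 * cond.peak_A.iloc[-1]

    def test_activities_bounded_and_far_from_saturation(self):
        df = run_rate_protocol(RateParams(), n_repeats=3, seed=2)
        for col in ("act_A", "act_B"):
            assert df[col].min() >= 0.0
            assert df[col].max() <= 1.0
            assert df[col].max() < 0.8  # 0.8 * k_X with k_X = 1

    def test_context_swap_symmetry_exact(self):
        # mirrored stimulus with identical parameters swaps the roles exactly
        params = RateParams(noise_sigma=0.0)
        fwd = run_rate_protocol(params, default_rate_protocol(), n_repeats=1, seed=0)
        swapped_phases = [
            RatePhase("conditioning", "B", 5),
            RatePhase("extinction", "A", 6),
        ]
        rev = run_rate_protocol(params, swapped_phases, n_repeats=1, seed=0)
        np.testing.assert_allclose(fwd.act_A.to_numpy(), rev.act_B.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(fwd.w_A_CS.to_numpy(), rev.w_B_CS.to_numpy(), atol=1e-12)

    def test_noise_free_runs_are_deterministic(self):
        params = RateParams(noise_sigma=0.0)
        a = run_rate_protocol(params, n_repeats=1, seed=1)
        b = run_rate_protocol(params, n_repeats=1, seed=99)
        np.testing.assert_array_equal(a.act_A.to_numpy(), b.act_A.to_numpy())
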