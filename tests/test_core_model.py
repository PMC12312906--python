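import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locolearn.core_model import (
    HeightClass,
    LearnerState,
    ObstacleSpec,
    OutputVariant,
    ParticipantParams,
    compute_error,
    context_vector,
    motor_output,
    simulate_fc_est_batch,
    simulate_sequence,
    state_update,
)

LOW = ObstacleSpec(HeightClass.LOW, 0.05, 0.05, 0.09)
HIGH = ObstacleSpec(HeightClass.HIGH, 0.18, 0.01, 0.05)


def make_params(B=0.1, q=0.0, tau=0.02, k=1.0, x1_low=0.20, x1_high=0.10):
    return ParticipantParams(B=B, q=q, tau=tau, k=k, x1_low=x1_low, x1_high=x1_high)


class TestObstacleSpec:
    def test_invalid_range(self):
        with pytest.raises(ValueError):
            ObstacleSpec(HeightClass.LOW, 0.05, 0.09, 0.05)

    def test_negative_height(self):
        with pytest.raises(ValueError):
            ObstacleSpec(HeightClass.LOW, -0.05, 0.05, 0.09)


class TestComputeError:
    def test_above_range(self):
        assert compute_error(0.12, LOW) == pytest.approx(-0.03)

    def test_inside_dead_zone(self):
        assert compute_error(0.07, LOW) == 0.0

    def test_below_range(self):
        assert compute_error(0.03, LOW) == pytest.approx(0.02)

    def test_closed_interval_boundaries(self):
        assert compute_error(0.05, LOW) == 0.0
        assert compute_error(0.09, LOW) == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            compute_error(float("nan"), LOW)
        with pytest.raises(ValueError):
            compute_error(float("inf"), LOW)


class TestContextVector:
    def test_low(self):
        assert context_vector(HeightClass.LOW, 0.5) == (1.0, 0.5)

    def test_high_no_interference(self):
        assert context_vector(HeightClass.HIGH, 0.0) == (0.0, 1.0)

    def test_high_full_interference(self):
        assert context_vector(HeightClass.HIGH, 1.0) == (1.0, 1.0)

    def test_q_out_of_range(self):
        with pytest.raises(ValueError):
            context_vector(HeightClass.LOW, 1.5)

    def test_unknown_height(self):
        with pytest.raises(ValueError):
            context_vector("MEDIUM", 0.5)


class TestMotorOutput:
    def test_dot_q_zero_reduces_to_selection(self):
        state = LearnerState(0.20, 0.10)
        assert motor_output(state, HeightClass.LOW, 0.0) == pytest.approx(0.20)

    def test_dot_blends_states(self):
        state = LearnerState(0.20, 0.10)
        assert motor_output(state, HeightClass.LOW, 0.5) == pytest.approx(0.25)

    def test_select_ignores_other_state(self):
        state = LearnerState(0.20, 0.10)
        out = motor_output(state, HeightClass.LOW, 0.5, OutputVariant.SELECT)
        assert out == pytest.approx(0.20)


class TestStateUpdate:
    def test_componentwise_arithmetic(self):
        state = LearnerState(0.20, 0.10)
        new = state_update(state, -0.04, HeightClass.LOW, make_params(B=0.5, q=0.5))
        assert new.x_low == pytest.approx(0.18)
        assert new.x_high == pytest.approx(0.09)
        assert new.trial_index == 2

    def test_zero_error_is_identity(self):
        state = LearnerState(0.123, 0.456)
        new = state_update(state, 0.0, HeightClass.HIGH, make_params(B=0.9, q=0.7))
        assert (new.x_low, new.x_high) == (0.123, 0.456)

    def test_full_interference_keeps_equal_states_equal(self):
        state = LearnerState(0.20, 0.20)
        new = state_update(state, -0.02, HeightClass.LOW, make_params(B=1.0, q=1.0))
        assert new.x_low == pytest.approx(0.18)
        assert new.x_high == pytest.approx(0.18)


class TestSimulateSequence:
    def test_geometric_closed_form(self):
        # q=0, all-LOW: x_{n+1} = 0.9 x_n + 0.009 while above the range,
        # so fc_est on trial n+1 is 0.09 + 0.11 * 0.9^n
        params = make_params(B=0.1, q=0.0, x1_low=0.20)
        sim = simulate_sequence(params, [LOW] * 11)
        assert sim[10].fc_est == pytest.approx(0.09 + 0.11 * 0.9**10, abs=1e-12)
        assert sim[10].fc_est == pytest.approx(0.128354628411, abs=1e-12)

    def test_zero_learning_rate_constant_output(self):
        params = make_params(B=0.0, q=0.3, x1_low=0.20, x1_high=0.10)
        sched = [LOW, HIGH] * 10
        sim = simulate_sequence(params, sched)
        low_outputs = {r.fc_est for r, s in zip(sim, sched) if s is LOW}
        high_outputs = {r.fc_est for r, s in zip(sim, sched) if s is HIGH}
        assert len(low_outputs) == 1 and len(high_outputs) == 1

    def test_matches_scalar_reference_loop(self):
        # independently coded scalar loop over a mixed 32-trial schedule
        params = make_params(B=0.14, q=0.45, x1_low=0.20, x1_high=0.12)
        rng = np.random.default_rng(0)
        sched = [LOW if rng.random() < 0.5 else HIGH for _ in range(32)]
        sim = simulate_sequence(params, sched)

        xl, xh = 0.20, 0.12
        for res, spec in zip(sim, sched):
            if spec.height_class is HeightClass.LOW:
                fc = xl + 0.45 * xh
                w = (1.0, 0.45)
            else:
                fc = 0.45 * xl + xh
                w = (0.45, 1.0)
            if fc > spec.h_upper:
                e = spec.h_upper - fc
            elif fc < spec.h_lower:
                e = spec.h_lower - fc
            else:
                e = 0.0
            assert res.fc_est == pytest.approx(fc, abs=1e-15)
            assert res.error == pytest.approx(e, abs=1e-15)
            xl += 0.14 * e * w[0]
            xh += 0.14 * e * w[1]

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError):
            simulate_sequence(make_params(), [])

    def test_noise_reproducible(self):
        params = make_params()
        a = simulate_sequence(params, [LOW] * 20, noise="student_t", nu=5, seed=42)
        b = simulate_sequence(params, [LOW] * 20, noise="student_t", nu=5, seed=42)
        assert [r.fc_observed for r in a] == [r.fc_observed for r in b]

    def test_noise_does_not_perturb_state_path(self):
        params = make_params()
        noisy = simulate_sequence(params, [LOW] * 20, noise="student_t", nu=5, seed=1)
        clean = simulate_sequence(params, [LOW] * 20)
        assert [r.fc_est for r in noisy] == [r.fc_est for r in clean]


class TestBatchSimulator:
    def test_matches_reference_on_random_draws(self, rng):
        n_draws, n_trials = 100, 64
        B = rng.uniform(0, 1, n_draws)
        q = rng.uniform(0, 1, n_draws)
        x1l = rng.uniform(0.05, 0.3, n_draws)
        x1h = rng.uniform(0.02, 0.2, n_draws)
        codes = rng.integers(0, 2, n_trials)
        sched = [LOW if c == 0 else HIGH for c in codes]
        h_lo = np.array([s.h_lower for s in sched])
        h_hi = np.array([s.h_upper for s in sched])
        for variant in OutputVariant:
            batch = simulate_fc_est_batch(B, q, x1l, x1h, codes, h_lo, h_hi, variant)
            for d in range(n_draws):
                params = make_params(B=B[d], q=q[d], x1_low=x1l[d], x1_high=x1h[d])
                ref = simulate_sequence(params, sched, variant=variant)
                np.testing.assert_allclose(
                    batch[d], [r.fc_est for r in ref], atol=1e-12, rtol=0
                )


@settings(max_examples=100, deadline=None)
@given(
    B=st.floats(0.0, 1.0),
    q=st.floats(0.0, 1.0),
    x_low=st.floats(0.051, 0.089),
    x_high=st.floats(0.30, 0.60),
)
def test_dead_zone_conservation(B, q, x_low, x_high):
    # LOW-context trial with output inside the dead zone leaves the state
    # exactly unchanged (SELECT keeps the output at x_low which is inside)
    params = make_params(B=B, q=q, x1_low=x_low, x1_high=x_high)
    sim = simulate_sequence(params, [LOW], variant=OutputVariant.SELECT)
    assert sim[0].error == 0.0
    assert (sim[0].state.x_low, sim[0].state.x_high) == (x_low, x_high)


@settings(max_examples=50, deadline=None)
@given(
    B=st.floats(0.0, 1.0),
    x0=st.floats(0.0, 0.5),
    n=st.integers(1, 50),
    seed=st.integers(0, 10_000),
)
def test_full_interference_symmetry(B, x0, n, seed):
    # q=1 with equal initial states keeps x_low == x_high forever
    rng = np.random.default_rng(seed)
    sched = [LOW if rng.random() < 0.5 else HIGH for _ in range(n)]
    params = make_params(B=B, q=1.0, x1_low=x0, x1_high=x0)
    for res in simulate_sequence(params, sched):
        assert res.state.x_low == res.state.x_high


@settings(max_examples=50, deadline=None)
@given(
    B=st.floats(0.0, 1.0),
    q=st.floats(0.0, 1.0),
    x_low=st.floats(0.0, 0.4),
    x_high=st.floats(0.0, 0.4),
)
def test_update_bounded_by_error(B, q, x_low, x_high):
    # the current context's state never moves farther than the error itself
    params = make_params(B=B, q=q, x1_low=x_low, x1_high=x_high)
    sim = simulate_sequence(params, [LOW, HIGH], variant=OutputVariant.SELECT)
    step_low = sim[1].state.x_low - sim[0].state.x_low
    assert abs(step_low) <= abs(sim[0].error) + 1e-15


def test_geometric_convergence_rate():
    # gap above h_upper decays by exactly (1 - B) per trial
    B = 0.25
    params = make_params(B=B, q=0.0, x1_low=0.30)
    sim = simulate_sequence(params, [LOW] * 12)
    gaps = [r.fc_est - LOW.h_upper for r in sim]
    for a, b in zip(gaps, gaps[1:]):
        if b > 0:
            assert b == pytest.approx((1 - B) * a, abs=1e-12)
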