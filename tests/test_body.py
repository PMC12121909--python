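import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecomotor.body import (
    BallisticPhaseError,
    BodyState,
    CommandSample,
    TrajectorySample,
    classify_outcome,
    com_position,
    default_body,
    frame_to_trajectory,
    perturbation_force,
    step_dynamics,
    trajectory_to_frame,
    zmp,
)
from ecomotor.body import _derivatives
from ecomotor.control import execute_trial
from ecomotor.feedback import FeedbackGains
from ecomotor.internal_model import InternalDynamicsModel

from conftest import make_plan


class TestPerturbationForce:
    @pytest.mark.parametrize(
        "y_dot,mass,K,expected",
        [(1.0, 77.0, 3.0, 231.0), (0.0, 77.0, 3.0, 0.0), (-0.3, 77.0, 3.0, 0.0)],
    )
    def test_printed_law(self, y_dot, mass, K, expected):
        assert perturbation_force(y_dot, mass, K) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            perturbation_force(float("nan"), 77.0, 3.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        y_dot=st.floats(0.01, 5.0),
        mass=st.floats(1.0, 200.0),
        scale=st.floats(0.1, 10.0),
    )
    def test_linear_in_velocity_and_mass(self, y_dot, mass, scale):
        base = perturbation_force(y_dot, mass, 3.0)
        assert base >= 0
        assert perturbation_force(scale * y_dot, mass, 3.0) == pytest.approx(
            scale * base, rel=1e-12
        )
        assert perturbation_force(y_dot, scale * mass, 3.0) == pytest.approx(
            scale * base, rel=1e-12
        )


class TestStepDynamics:
    def test_static_equilibrium(self, body):
        state = BodyState(r=body.leg_length_stand, theta=0.0, r_dot=0.0, theta_dot=0.0)
        cmd = CommandSample(force_prismatic=body.mass_total * body.gravity, torque_ankle=0.0)
        params = dataclasses.replace(body, perturbation_gain_K=0.0)
        for _ in range(100):
            state = step_dynamics(state, cmd, params, 1e-3)
        assert abs(state.r - body.leg_length_stand) < 1e-9
        assert abs(state.theta) < 1e-9

    def test_inverted_pendulum_closed_form(self, unperturbed):
        # with the leg length held fixed and a small initial tilt, the
        # linearized inverted pendulum diverges as cosh(t*sqrt(g/r))
        r0, th0 = 1.0, 0.01
        params = dataclasses.replace(unperturbed, leg_length_stand=1.2, leg_length_squat=0.5)
        state = BodyState(r=r0, theta=th0, r_dot=0.0, theta_dot=0.0)
        m, g = params.mass_total, params.gravity
        t_end = 0.5
        n = 500
        for _ in range(n):
            # prismatic force chosen so rddot = 0 (leg locked)
            F = m * (g * math.cos(state.theta) - r0 * state.theta_dot**2)
            state = step_dynamics(state, CommandSample(F, 0.0), params, t_end / n)
        expected = th0 * math.cosh(t_end * math.sqrt(g / r0))
        assert state.theta == pytest.approx(expected, rel=0.01)
        assert state.r == pytest.approx(r0, abs=1e-6)

    def test_perturbation_acceleration_component(self, body):
        # rising straight up at 1 m/s: the pull contributes -K*ydot = -3 m/s^2
        # of horizontal COM acceleration (theta = 0: all of it is rotational)
        m, g, K = body.mass_total, body.gravity, body.perturbation_gain_K
        r = 0.8
        d_pert = _derivatives(r, 0.0, 1.0, 0.0, m * g, 0.0, m, g, K)
        d_free = _derivatives(r, 0.0, 1.0, 0.0, m * g, 0.0, m, g, 0.0)
        # horizontal accel difference = r*(thdd_pert - thdd_free) at theta=0
        xdd_delta = r * (d_pert[3] - d_free[3])
        assert xdd_delta == pytest.approx(-K * 1.0, rel=1e-12)

    def test_matches_fine_euler_oracle(self, body):
        # independent integrator: explicit Euler at dt/100
        m, g, K = body.mass_total, body.gravity, body.perturbation_gain_K
        cmd = CommandSample(force_prismatic=m * g * 1.05, torque_ankle=5.0)
        s_rk = BodyState(r=0.7, theta=0.05, r_dot=0.1, theta_dot=0.0)
        dt = 1e-3
        n = 1200
        for _ in range(n):
            s_rk = step_dynamics(s_rk, cmd, body, dt)
        r, th, rd, thd = 0.7, 0.05, 0.1, 0.0
        h = dt / 100
        for _ in range(n * 100):
            d = _derivatives(r, th, rd, thd, cmd.force_prismatic, cmd.torque_ankle, m, g, K)
            r, th, rd, thd = r + h * d[0], th + h * d[1], rd + h * d[2], thd + h * d[3]
        x_rk, y_rk = com_position(s_rk)
        x_e = r * math.sin(th)
        y_e = r * math.cos(th)
        assert abs(x_rk - x_e) < 1e-4
        assert abs(y_rk - y_e) < 1e-4

    def test_rejects_large_step(self, body):
        state = BodyState(r=0.7, theta=0.0, r_dot=0.0, theta_dot=0.0)
        with pytest.raises(ValueError):
            step_dynamics(state, CommandSample(0, 0), body, 0.01)

    def test_work_energy_balance(self, unperturbed):
        # unperturbed actuated motion: energy change equals actuator work
        m, g = unperturbed.mass_total, unperturbed.gravity
        state = BodyState(r=0.6, theta=0.02, r_dot=0.0, theta_dot=0.0)
        cmd = CommandSample(force_prismatic=m * g * 1.02, torque_ankle=-2.0)
        dt = 1e-3
        work = 0.0
        e0 = 0.5 * m * (state.r_dot**2 + (state.r * state.theta_dot) ** 2) + (
            m * g * state.r * math.cos(state.theta)
        )
        for _ in range(1200):
            prev = state
            state = step_dynamics(state, cmd, unperturbed, dt)
            work += cmd.force_prismatic * 0.5 * (prev.r_dot + state.r_dot) * dt
            work += cmd.torque_ankle * 0.5 * (prev.theta_dot + state.theta_dot) * dt
        e1 = 0.5 * m * (state.r_dot**2 + (state.r * state.theta_dot) ** 2) + (
            m * g * state.r * math.cos(state.theta)
        )
        assert e1 - e0 == pytest.approx(work, rel=1e-3)


class TestZmp:
    def test_static_projection(self, body):
        state = BodyState(r=1.0, theta=0.1, r_dot=0.0, theta_dot=0.0)
        x, _ = com_position(state)
        assert zmp(state, (0.0, 0.0), body) == pytest.approx(x)

    def test_printed_formula(self, body):
        # x=0, y=1, xdd=-1, ydd=0 -> zmp = +1/9.81 = 0.10194
        state = BodyState(r=1.0, theta=0.0, r_dot=0.0, theta_dot=0.0)
        assert zmp(state, (-1.0, 0.0), body) == pytest.approx(0.10194, abs=1e-5)

    def test_ballistic_error(self, body):
        state = BodyState(r=1.0, theta=0.0, r_dot=0.0, theta_dot=0.0)
        with pytest.raises(BallisticPhaseError):
            zmp(state, (0.0, -2 * body.gravity), body)

    def test_backward_force_shifts_zmp_backward(self, body, unperturbed, adapted_model):
        # same plan executed with and without the pull: the balance point
        # of the pulled trial lies further backward
        import copy

        gains = FeedbackGains()
        plan = make_plan(body, (0.05, 0.09, 0.10))
        model_p = copy.deepcopy(adapted_model)
        model_u = InternalDynamicsModel(params=unperturbed)
        tr_p = execute_trial(plan, body, model_p, gains, learn=False).trajectory
        tr_u = execute_trial(plan, unperturbed, model_u, gains, learn=False).trajectory
        assert min(s.zmp_x for s in tr_p) < min(s.zmp_x for s in tr_u)


class TestClassifyOutcome:
    def test_unperturbed_standup_succeeds(self, body, unperturbed):
        model = InternalDynamicsModel(params=unperturbed)
        res = execute_trial(make_plan(body), unperturbed, model, FeedbackGains())
        assert classify_outcome(res.trajectory, unperturbed) == "success"

    def test_first_perturbed_trial_falls_backward(self, body, unperturbed):
        model = InternalDynamicsModel(params=unperturbed)
        res = execute_trial(make_plan(body), body, model, FeedbackGains())
        assert classify_outcome(res.trajectory, body) == "failure_backward"

    def test_catch_after_adaptation_falls_forward(self, body, unperturbed, adapted_model):
        import copy

        model = copy.deepcopy(adapted_model)
        plan = make_plan(body, (0.05, 0.09, 0.10))
        res = execute_trial(plan, unperturbed, model, FeedbackGains())
        assert classify_outcome(res.trajectory, unperturbed) == "failure_forward"

    def test_empty_trajectory_rejected(self, body):
        with pytest.raises(ValueError):
            classify_outcome([], body)


def test_trajectory_csv_roundtrip(body, unperturbed):
    model = InternalDynamicsModel(params=unperturbed)
    traj = execute_trial(make_plan(body), unperturbed, model, FeedbackGains()).trajectory
    df = trajectory_to_frame(traj)
    back = frame_to_trajectory(df)
    assert len(back) == len(traj)
    assert back[10] == traj[10]


def test_body_params_validation():
    with pytest.raises(ValueError):
        default_body(mass_total=-1.0)
    with pytest.raises(ValueError):
        default_body(perturbation_gain_K=-0.5)
    with pytest.raises(ValueError):
        default_body(leg_length_squat=1.5)
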