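"""Per-trial closed-loop executor.

Runs one squat-to-stand trial: the planned COM reference is tracked by the
feed-forward command from the internal model plus the scaled PD feedback,
the body is integrated by fixed-step RK4 (1 ms) with a zero-order-hold
command per control tick (5 ms), and the internal model learns from the
issued net command and the observed acceleration after every tick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .body import (
    BodyParams,
    BodyState,
    CommandSample,
    SimulationDivergedError,
    TrajectorySample,
    com_acceleration,
    com_position,
    com_velocity,
    step_dynamics,
    zmp,
)
from .feedback import FeedbackGains, feedback_command, tune_multiplier
from .internal_model import (
    InternalDynamicsModel,
    feedforward_command,
    observe_and_learn,
)
from .plan import MotorPlan, plan_to_reference

__all__ = ["ExecutionResult", "execute_trial"]

DT_DYNAMICS = 1e-3
DT_CONTROL = 5e-3

FORCE_LIMIT = 4000.0
TORQUE_LIMIT = 400.0


@dataclass
class ExecutionResult:
    trajectory: list[TrajectorySample]
    feedback_multiplier_mean: float
    diverged: bool = False


def execute_trial(
    plan: MotorPlan,
    params: BodyParams,
    model: InternalDynamicsModel,
    gains: FeedbackGains,
    learn: bool = True,
    dt_control: float = DT_CONTROL,
    dt_dynamics: float = DT_DYNAMICS,
) -> ExecutionResult:
    """Execute one trial; mutates ``model`` if ``learn`` is True.

    ``params.perturbation_gain_K`` decides whether the pull is active; the
    internal model always carries its own (possibly stale) belief.
    """
    ref = plan_to_reference(plan, dt_control)
    state = BodyState(r=plan.start[1], theta=math.asin(
        plan.start[0] / plan.start[1]), r_dot=0.0, theta_dot=0.0, t=0.0)
    substeps = max(1, int(round(dt_control / dt_dynamics)))
    m, K = params.mass_total, params.perturbation_gain_K

    trajectory: list[TrajectorySample] = []
    mult_sum = 0.0
    diverged = False
    for row in ref:
        _, xd, yd, vxd, vyd, axd, ayd = row
        x, y = com_position(state)
        vx, vy = com_velocity(state)
        gains = tune_multiplier(gains, model.prediction_error_trace)
        mult_sum += gains.multiplier_g
        u_ff = feedforward_command(model, state, (axd, ayd))
        u_fb = feedback_command(
            gains, state, (xd - x, yd - y), (vxd - vx, vyd - vy)
        )
        F = min(FORCE_LIMIT, max(-FORCE_LIMIT, u_ff.force_prismatic + u_fb.force_prismatic))
        tau = min(TORQUE_LIMIT, max(-TORQUE_LIMIT, u_ff.torque_ankle + u_fb.torque_ankle))
        u_net = CommandSample(force_prismatic=F, torque_ankle=tau, t=state.t)

        axx, ayy = com_acceleration(state, u_net, params)
        f_ext = -K * m * vy if vy > 0.0 else 0.0
        try:
            zx = zmp(state, (axx, ayy), params, f_ext_x=f_ext)
        except ValueError:
            zx = x  # ballistic instant: fall back to the ground projection
        trajectory.append(
            TrajectorySample(
                x=x, y=y, x_dot=vx, y_dot=vy, x_ddot=axx, y_ddot=ayy,
                zmp_x=zx, t=state.t, force_prismatic=F, torque_ankle=tau,
            )
        )
        if learn:
            observe_and_learn(model, u_net, state, (axx, ayy))
        try:
            for _ in range(substeps):
                state = step_dynamics(state, u_net, params, dt_dynamics)
        except SimulationDivergedError:
            diverged = True
            break

    n = len(trajectory)
    return ExecutionResult(
        trajectory=trajectory,
        feedback_multiplier_mean=mult_sum / max(n, 1),
        diverged=diverged,
    )
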