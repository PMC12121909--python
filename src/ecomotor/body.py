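"""Two degree-of-freedom inverted-pendulum body for squat-to-stand simulation.

The body is a point mass at distance ``r`` (prismatic joint, the "leg") from
the ankle, at angle ``theta`` from the vertical (positive forward).  A
translational actuator pushes along the leg and a rotational actuator applies
torque at the ankle.  While the centre of mass (COM) moves upward, an external
horizontal pulling force proportional to the vertical COM velocity drags the
body backward:

    F_pert = K * max(ydot, 0) * m        (applied along -x)

Coordinates: +x is forward (against the perturbation), +y is up, origin at
the ankle.  COM position is (x, y) = (r sin(theta), r cos(theta)).

Equations of motion (Lagrangian of a point mass in polar coordinates with
generalized actuator forces and an external horizontal force F_x at the COM):

    rddot  = F/m + r thetadot^2 - g cos(theta) + (F_x/m) sin(theta)
    thddot = tau/(m r^2) - 2 rdot thetadot / r + (g/r) sin(theta)
             + (F_x/(m r)) cos(theta)

Integration is fixed-step RK4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BodyParams",
    "BodyState",
    "CommandSample",
    "TrajectorySample",
    "SimulationDivergedError",
    "BallisticPhaseError",
    "perturbation_force",
    "step_dynamics",
    "zmp",
    "classify_outcome",
    "com_position",
    "com_velocity",
    "trajectory_to_frame",
    "frame_to_trajectory",
    "default_body",
]


class SimulationDivergedError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""

    def __init__(self, t: float):
        super().__init__(f"simulation diverged at t={t:.4f} s")
        self.t = t


class BallisticPhaseError(ValueError):
    """ZMP is undefined when the net vertical ground reaction vanishes."""


@dataclass(frozen=True)
class BodyParams:
    """Physical parameters of the pendulum body and its environment.

    ``perturbation_gain_K`` is the pull gain in 1/s: the backward force is
    K * ydot * mass while the COM moves up.  The support interval
    [foot_support_back, foot_support_front] is the range of admissible
    zero-moment-point positions (the foot, heel to toe, around the ankle).
    """

    mass_total: float = 77.0
    leg_length_squat: float = 0.55
    leg_length_stand: float = 1.05
    foot_support_front: float = 0.17
    foot_support_back: float = -0.08
    gravity: float = 9.81
    perturbation_gain_K: float = 3.0
    #: habitual forward offset of the COM over the ankle in quiet stance
    #: (the COM of a standing human projects near mid-foot, not the ankle)
    stance_x: float = 0.05

    def __post_init__(self):
        if not self.mass_total > 0:
            raise ValueError("mass_total must be positive")
        if not 0 < self.leg_length_squat < self.leg_length_stand:
            raise ValueError("require 0 < leg_length_squat < leg_length_stand")
        if not self.foot_support_back < 0 < self.foot_support_front:
            raise ValueError("support interval must straddle the ankle")
        if self.perturbation_gain_K < 0:
            raise ValueError("perturbation gain must be non-negative")

    @property
    def com_rise(self) -> float:
        return self.leg_length_stand - self.leg_length_squat


@dataclass(frozen=True)
class BodyState:
    """Configuration of the pendulum at one instant."""

    r: float
    theta: float
    r_dot: float
    theta_dot: float
    t: float = 0.0

    def is_finite(self) -> bool:
        return all(
            math.isfinite(v)
            for v in (self.r, self.theta, self.r_dot, self.theta_dot, self.t)
        )


@dataclass(frozen=True)
class CommandSample:
    """Actuator command: force along the leg and torque at the ankle."""

    force_prismatic: float
    torque_ankle: float
    t: float = 0.0


@dataclass(frozen=True)
class TrajectorySample:
    """COM kinematics, balance point and commands at one sample instant."""

    x: float
    y: float
    x_dot: float
    y_dot: float
    x_ddot: float
    y_ddot: float
    zmp_x: float
    t: float
    force_prismatic: float = 0.0
    torque_ankle: float = 0.0


def com_position(state: BodyState) -> tuple[float, float]:
    return state.r * math.sin(state.theta), state.r * math.cos(state.theta)


def com_velocity(state: BodyState) -> tuple[float, float]:
    s, c = math.sin(state.theta), math.cos(state.theta)
    xd = state.r_dot * s + state.r * state.theta_dot * c
    yd = state.r_dot * c - state.r * state.theta_dot * s
    return xd, yd


def perturbation_force(y_dot: float, mass: float, K: float) -> float:
    """Signed horizontal pulling force (along -x) for upward COM velocity.

    Returns the magnitude of the backward pull, K*max(y_dot,0)*mass; the pull
    is clamped to zero while the COM moves downward.
    """
    if not (math.isfinite(y_dot) and math.isfinite(mass) and math.isfinite(K)):
        raise ValueError("perturbation_force requires finite inputs")
    return K * max(y_dot, 0.0) * mass


def _derivatives(
    r: float,
    th: float,
    rd: float,
    thd: float,
    F: float,
    tau: float,
    m: float,
    g: float,
    K: float,
) -> tuple[float, float, float, float]:
    s = math.sin(th)
    c = math.cos(th)
    ydot = rd * c - r * thd * s
    fx = -K * m * ydot if ydot > 0.0 else 0.0  # backward pull
    rdd = F / m + r * thd * thd - g * c + fx * s / m
    thdd = tau / (m * r * r) - 2.0 * rd * thd / r + g * s / r + fx * c / (m * r)
    return rd, thd, rdd, thdd


def step_dynamics(
    state: BodyState, command: CommandSample, params: BodyParams, dt: float
) -> BodyState:
    """Advance the body by one RK4 step under a zero-order-hold command."""
    if not 0 < dt <= 5e-3:
        raise ValueError("dt must lie in (0, 5 ms]")
    if not state.is_finite():
        raise SimulationDivergedError(state.t)
    m, g, K = params.mass_total, params.gravity, params.perturbation_gain_K
    F, tau = command.force_prismatic, command.torque_ankle
    r, th, rd, thd = state.r, state.theta, state.r_dot, state.theta_dot

    k1 = _derivatives(r, th, rd, thd, F, tau, m, g, K)
    h = dt * 0.5
    k2 = _derivatives(
        r + h * k1[0], th + h * k1[1], rd + h * k1[2], thd + h * k1[3], F, tau, m, g, K
    )
    k3 = _derivatives(
        r + h * k2[0], th + h * k2[1], rd + h * k2[2], thd + h * k2[3], F, tau, m, g, K
    )
    k4 = _derivatives(
        r + dt * k3[0],
        th + dt * k3[1],
        rd + dt * k3[2],
        thd + dt * k3[3],
        F,
        tau,
        m,
        g,
        K,
    )
    sixth = dt / 6.0
    new = BodyState(
        r=r + sixth * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]),
        theta=th + sixth * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]),
        r_dot=rd + sixth * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]),
        theta_dot=thd + sixth * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]),
        t=state.t + dt,
    )
    if not new.is_finite():
        raise SimulationDivergedError(state.t + dt)
    return new


def com_acceleration(
    state: BodyState, command: CommandSample, params: BodyParams
) -> tuple[float, float]:
    """Instantaneous COM Cartesian acceleration under the given command."""
    m, g, K = params.mass_total, params.gravity, params.perturbation_gain_K
    _, _, rdd, thdd = _derivatives(
        state.r,
        state.theta,
        state.r_dot,
        state.theta_dot,
        command.force_prismatic,
        command.torque_ankle,
        m,
        g,
        K,
    )
    s, c = math.sin(state.theta), math.cos(state.theta)
    r, rd, thd = state.r, state.r_dot, state.theta_dot
    xdd = rdd * s + 2 * rd * thd * c + r * thdd * c - r * thd * thd * s
    ydd = rdd * c - 2 * rd * thd * s - r * thdd * s - r * thd * thd * c
    return xdd, ydd


def zmp(
    state: BodyState,
    accel: tuple[float, float],
    params: BodyParams,
    f_ext_x: float = 0.0,
) -> float:
    """Zero-moment point of the point-mass body.

    For the isolated body (``f_ext_x = 0``) this is the textbook formula
    x - y*xddot/(yddot + g).  When an external horizontal force acts at the
    COM (the pulling perturbation), the moment it exerts about the ankle must
    enter the ground-reaction balance, giving

        zmp = x - y*(m*xddot - f_ext_x) / (m*(yddot + g)).
    """
    xdd, ydd = accel
    g = params.gravity
    if ydd + g <= 0:
        raise BallisticPhaseError("ZMP undefined: vertical ground reaction <= 0")
    x, y = com_position(state)
    m = params.mass_total
    return x - y * (m * xdd - f_ext_x) / (m * (ydd + g))


def classify_outcome(
    trajectory: Sequence[TrajectorySample],
    params: BodyParams,
    grace_time: float = 0.040,
    height_tol: float = 0.05,
) -> str:
    """Label a trial success / failure_backward / failure_forward.

    Success requires the final COM height to be within ``height_tol`` of the
    standing height and balance to be maintained throughout, allowing
    excursions shorter than ``grace_time`` (the model's analogue of "no
    corrective step needed").  Two balance-loss signals are checked:

    * the COM itself leaving the support interval — unrecoverable once the
      COM passes the toe or heel, so it dominates and sets the direction
      (this is what makes an unannounced removal of the pull a *forward*
      fall: the learned compensation launches the COM over the toes);
    * the balance point (zmp_x) leaving the support interval for longer than
      the grace time — the "corrective step" analogue, direction given by
      the first sustained excursion.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    lo, hi = params.foot_support_back, params.foot_support_front

    def first_sustained_excursion(values: Sequence[float]) -> int:
        start = None
        cur = 0
        for s, v in zip(trajectory, values):
            sign = -1 if v < lo else (1 if v > hi else 0)
            if sign == 0:
                start, cur = None, 0
            else:
                if start is None or sign != cur:
                    start, cur = s.t, sign
                elif s.t - start > grace_time:
                    return cur
        return 0

    com_exit = first_sustained_excursion([s.x for s in trajectory])
    if com_exit:
        return "failure_forward" if com_exit > 0 else "failure_backward"
    zmp_exit = first_sustained_excursion([s.zmp_x for s in trajectory])
    if zmp_exit:
        return "failure_forward" if zmp_exit > 0 else "failure_backward"
    last = trajectory[-1]
    if abs(last.y - params.leg_length_stand) <= height_tol:
        return "success"
    # upright finish was not reached although balance never broke down
    return "failure_backward" if last.x < 0 else "failure_forward"


_TRAJ_COLUMNS = [
    "t",
    "x",
    "y",
    "x_dot",
    "y_dot",
    "x_ddot",
    "y_ddot",
    "zmp_x",
    "force_prismatic",
    "torque_ankle",
]


def trajectory_to_frame(trajectory: Sequence[TrajectorySample]) -> pd.DataFrame:
    """Serialize a trial trajectory to the documented CSV column layout."""
    return pd.DataFrame(
        [[getattr(s, c) for c in _TRAJ_COLUMNS] for s in trajectory],
        columns=_TRAJ_COLUMNS,
    )


def frame_to_trajectory(df: pd.DataFrame) -> list[TrajectorySample]:
    return [
        TrajectorySample(
            x=row.x,
            y=row.y,
            x_dot=row.x_dot,
            y_dot=row.y_dot,
            x_ddot=row.x_ddot,
            y_ddot=row.y_ddot,
            zmp_x=row.zmp_x,
            t=row.t,
            force_prismatic=getattr(row, "force_prismatic", 0.0),
            torque_ankle=getattr(row, "torque_ankle", 0.0),
        )
        for row in df.itertuples()
    ]


def default_body(**overrides) -> BodyParams:
    """Default body: 77 kg, COM rise 0.5 m, pull gain K = 3 /s."""
    return replace(BodyParams(), **overrides) if overrides else BodyParams()
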