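"""PD feedback on COM tracking error with an adaptively scaled gain.

Fixed proportional and derivative gains act on the Cartesian COM error; the
resulting virtual force is mapped to actuator space through the transpose of
the configuration Jacobian.  A single scalar multiplier scales the whole
feedback command and is tied to the internal model's prediction-error trace
by a fixed relation: the multiplier is proportional to the error trace and
saturates at a cap, so feedback gains are inversely related to internal-model
accuracy and decay toward zero as the model converges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .body import BodyState, CommandSample

__all__ = ["FeedbackGains", "feedback_command", "tune_multiplier"]


@dataclass(frozen=True)
class FeedbackGains:
    """Fixed PD gains with an adaptable scalar multiplier."""

    kp: tuple[float, float] = (1500.0, 1500.0)  # N/m on (x, y) COM error
    kd: tuple[float, float] = (250.0, 250.0)  # N s/m on COM velocity error
    multiplier_g: float = 0.0
    relation_scale_c: float = 1.5  # multiplier per (m/s^2) of prediction error
    multiplier_cap: float = 3.0

    def __post_init__(self):
        if min(*self.kp, *self.kd) < 0:
            raise ValueError("PD gains must be non-negative")
        if not 0 <= self.multiplier_g <= self.multiplier_cap:
            raise ValueError("multiplier must lie in [0, cap]")


def feedback_command(
    gains: FeedbackGains,
    state: BodyState,
    pos_error: tuple[float, float],
    vel_error: tuple[float, float],
) -> CommandSample:
    """Scaled PD command, COM-space error mapped via the Jacobian transpose.

    The virtual Cartesian force f = g*(kp o e_pos + kd o e_vel) becomes a
    prismatic force f . (sin, cos) and an ankle torque r*(fx cos - fy sin).
    """
    fx = gains.multiplier_g * (
        gains.kp[0] * pos_error[0] + gains.kd[0] * vel_error[0]
    )
    fy = gains.multiplier_g * (
        gains.kp[1] * pos_error[1] + gains.kd[1] * vel_error[1]
    )
    s, c = math.sin(state.theta), math.cos(state.theta)
    return CommandSample(
        force_prismatic=fx * s + fy * c,
        torque_ankle=state.r * (fx * c - fy * s),
        t=state.t,
    )


def tune_multiplier(
    gains: FeedbackGains, prediction_error_trace: float
) -> FeedbackGains:
    """Set the multiplier from the prediction-error trace (capped linear)."""
    if prediction_error_trace < 0:
        raise ValueError("prediction error trace must be non-negative")
    g = min(
        gains.multiplier_cap, gains.relation_scale_c * prediction_error_trace
    )
    return replace(gains, multiplier_g=g)
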