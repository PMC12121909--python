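"""Adaptive inverse-dynamics internal model.

The feed-forward controller is initialised with the *exact* inverse dynamics
of the unperturbed body (closed form from the point-mass equations of motion
with the pull gain set to zero) plus a learnable additive correction that is
linear in a fixed feature basis of the state.  The correction is adapted
online by normalized-LMS gradient descent on the command-space prediction
error (feedback-error learning): after every control tick the model predicts
the command that would have produced the observed acceleration and moves its
weights toward the actually issued net command.  A running RMS of the
prediction error, expressed in acceleration-equivalent units, is exposed for
feedback-gain tuning.

The base model is exact in the unperturbed environment, so the only dynamics
error the correction must capture is the pull; the feature basis is the
ydot-proportional force family (ydot, ydot*sin(theta), ydot*r*cos(theta) per
channel).  The true velocity-proportional pull is exactly representable in
it, the learned weights converge to the generative law K*ydot*m, and —
because the basis vanishes whenever the COM is not rising — the correction
generalizes across motor plans instead of memorising plan-specific residue.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .body import BodyParams, BodyState, CommandSample

__all__ = [
    "InternalDynamicsModel",
    "base_inverse_dynamics",
    "feedforward_command",
    "observe_and_learn",
    "shift_toward_unperturbed",
]

N_FEATURES = 3


def _features(state: BodyState) -> np.ndarray:
    s, c = math.sin(state.theta), math.cos(state.theta)
    ydot = state.r_dot * c - state.r * state.theta_dot * s
    return np.array([ydot, ydot * s, ydot * state.r * c])


def base_inverse_dynamics(
    state: BodyState, desired_accel: tuple[float, float], params: BodyParams
) -> tuple[float, float]:
    """Exact unperturbed inverse dynamics of the point-mass pendulum.

    Decomposing the required Cartesian COM force m*(a + g e_y) onto the leg
    axis (prismatic force) and its perpendicular (ankle torque / r):

        F   = m*(ax*sin(theta) + (ay + g)*cos(theta))
        tau = m*r*(ax*cos(theta) - (ay + g)*sin(theta))
    """
    ax, ay = desired_accel
    m, g = params.mass_total, params.gravity
    s, c = math.sin(state.theta), math.cos(state.theta)
    F = m * (ax * s + (ay + g) * c)
    tau = m * state.r * (ax * c - (ay + g) * s)
    return F, tau


@dataclass
class InternalDynamicsModel:
    """Base inverse dynamics plus a linear additive correction per channel."""

    params: BodyParams
    delta_weights: np.ndarray = None  # shape (2, N_FEATURES): (force, torque)
    learning_rate_eta: float = 0.003
    prediction_error_trace: float = 0.0
    trace_decay: float = 0.02  # EMA factor per observed tick

    def __post_init__(self):
        if self.delta_weights is None:
            self.delta_weights = np.zeros((2, N_FEATURES))
        else:
            self.delta_weights = np.asarray(self.delta_weights, dtype=float)

    def additive_command(self, state: BodyState) -> tuple[float, float]:
        phi = _features(state)
        dF, dtau = self.delta_weights @ phi
        return float(dF), float(dtau)

    def to_json(self) -> str:
        return json.dumps(
            {
                "delta_weights": self.delta_weights.tolist(),
                "learning_rate_eta": self.learning_rate_eta,
                "prediction_error_trace": self.prediction_error_trace,
                "trace_decay": self.trace_decay,
            }
        )


def feedforward_command(
    model: InternalDynamicsModel,
    state: BodyState,
    desired_accel: tuple[float, float],
) -> CommandSample:
    """Base inverse-dynamics command plus the learned additive term."""
    F, tau = base_inverse_dynamics(state, desired_accel, model.params)
    dF, dtau = model.additive_command(state)
    return CommandSample(
        force_prismatic=F + dF, torque_ankle=tau + dtau, t=state.t
    )


def observe_and_learn(
    model: InternalDynamicsModel,
    net_command: CommandSample,
    state: BodyState,
    observed_accel: tuple[float, float],
) -> InternalDynamicsModel:
    """Normalized-LMS update of the additive weights from one observation.

    The command that the current model would predict for the observed
    acceleration is compared against the actually issued net command; the
    residual drives the weight update and (in acceleration-equivalent units)
    the running prediction-error trace.  The update mutates and returns the
    model (the object is a stateful learner).
    """
    F_pred, tau_pred = base_inverse_dynamics(state, observed_accel, model.params)
    phi = _features(state)
    dF, dtau = model.delta_weights @ phi
    err = np.array(
        [
            net_command.force_prismatic - (F_pred + dF),
            net_command.torque_ankle - (tau_pred + dtau),
        ]
    )
    norm = phi @ phi + 1.0
    model.delta_weights += (
        model.learning_rate_eta / norm
    ) * np.outer(err, phi)
    m, r = model.params.mass_total, max(state.r, 1e-6)
    e_acc = math.hypot(err[0] / m, err[1] / (m * r))
    b = model.trace_decay
    model.prediction_error_trace = math.sqrt(
        (1 - b) * model.prediction_error_trace**2 + b * e_acc**2
    )
    return model


def shift_toward_unperturbed(
    model: InternalDynamicsModel, rho: float
) -> InternalDynamicsModel:
    """Shrink the additive correction toward the unperturbed model by rho."""
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    model.delta_weights = (1.0 - rho) * model.delta_weights
    return model
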