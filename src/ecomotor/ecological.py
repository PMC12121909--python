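"""Ecological control: success-efficient/failure-safe cost arbitration.

The top layer of the hierarchy labels each trial outcome and decides which
cost the reinforcement learner optimises.  Learning starts in *safe* mode
(the cost penalises backward excursions of the zero-moment point).  Once a
per-run "confidence" threshold of accumulated successes is reached — drawn
once per run from Normal(50, 50), truncated below at 1 — the learner switches
to *efficient* mode and minimises effort instead, a win-stay/lose-shift-like
strategy.  Any failure drops the learner back to safe mode, restores the
remembered safe plan, and biases the next samples toward safety; confidence
progress is retained.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .body import BodyParams
from .plan import MotorPlan, PlanMemory

__all__ = [
    "EcologicalState",
    "RewardSpec",
    "draw_confidence_threshold",
    "safety_cost",
    "effort_cost",
    "compose_reward",
    "transition",
]


#: per-failure corrective nudge of the remembered safe plan (m per via),
#: applied against the direction of the fall
PLAN_CORRECTION_STEP = (0.003, 0.005, 0.006)


def draw_confidence_threshold(rng: np.random.Generator) -> int:
    """Successes required before effort optimisation engages: N(50,50), >= 1."""
    return max(1, int(round(rng.normal(50.0, 50.0))))


@dataclass
class EcologicalState:
    """Mode, success ledger, confidence threshold and safe-plan memory."""

    mode: str = "safe"  # {"safe", "efficient"}
    success_count: int = 0
    confidence_threshold: int = 50
    safety_bias: float = 0.0
    memory: PlanMemory = field(default_factory=PlanMemory)
    confidence_attained: bool = False
    pending_reset: MotorPlan | None = None
    bias_decay_per_success: float = 1.0 / 3.0
    #: forward-bias increment per backward fall while no safe plan is known;
    #: the bias builds up over repeated early failures rather than jumping
    bias_gain_per_failure: float = 0.15


@dataclass(frozen=True)
class RewardSpec:
    """Weights of the composite switching reward."""

    success_bonus: float = 1.0
    safety_weight: float = 0.6
    effort_weight: float = 0.4
    active_cost: str = "safety"  # {"safety", "effort"}

    def __post_init__(self):
        if min(self.success_bonus, self.safety_weight, self.effort_weight) < 0:
            raise ValueError("weights must be non-negative")
        if self.active_cost not in ("safety", "effort"):
            raise ValueError("active_cost must be 'safety' or 'effort'")


def safety_cost(trial, params: BodyParams) -> float:
    """Backward-excursion cost of the balance point, 0 at the toe, 1 at heel.

    Decreasing in the minimum forward margin of the recorded zero-moment
    point, and saturated at zero once the balance point stays forward of
    the ankle: cost = max(0, -min_t zmp_x / |back|).  A trial whose balance
    point never crosses behind the ankle is maximally safe (so there is no
    gradient toward pinning the balance point at the toe); at the backward
    support bound the cost is 1, and deeper backward excursions cost
    proportionally more.
    """
    zmps = [s.zmp_x for s in trial.trajectory]
    if not zmps:
        raise ValueError("trial has no zmp trace")
    return max(0.0, -min(zmps) / -params.foot_support_back)


def effort_cost(
    trial, force_scale: float = 755.0, torque_scale: float = 130.0
) -> float:
    """Time integral of squared normalized actuator commands over the trial.

    Commands are normalized by a nominal gravity-support force and an ankle
    torque scale so the two channels contribute comparably.
    """
    traj = trial.trajectory
    if not traj:
        raise ValueError("trial has no command trace")
    ts = np.array([s.t for s in traj])
    f = np.array([s.force_prismatic for s in traj]) / force_scale
    tau = np.array([s.torque_ankle for s in traj]) / torque_scale
    return float(np.trapezoid(f**2 + tau**2, ts))


def compose_reward(
    outcome: str, spec: RewardSpec, safety: float, effort: float
) -> float:
    """Success bonus minus the active cost; failure forfeits the bonus."""
    if min(safety, effort) < 0:
        raise ValueError("costs must be non-negative")
    cost = safety if spec.active_cost == "safety" else effort
    weight = (
        spec.safety_weight if spec.active_cost == "safety" else spec.effort_weight
    )
    bonus = spec.success_bonus if outcome == "success" else 0.0
    return bonus - weight * cost


def transition(
    state: EcologicalState, outcome: str, executed_plan: MotorPlan
) -> EcologicalState:
    """Advance the arbitration state after one labelled trial.

    Success: increment the ledger, remember the plan as the safe plan while
    in safe mode, decay the safety bias, and switch to efficient mode once
    the confidence threshold is reached.  Failure: revert to safe mode
    (confidence progress retained), schedule a reset of the policy mean to
    the remembered safe plan (if any), and adjust the safety bias
    *directionally*: a backward fall (the direction of the pull) raises the
    forward bias, while a forward fall — an over-lean — clears it.
    """
    state.pending_reset = None
    if outcome == "success":
        state.success_count += 1
        if state.mode == "safe":
            # consolidate rather than overwrite: the remembered safe plan
            # drifts toward the centroid of safe successes instead of
            # chasing the latest (possibly marginal) one
            if state.memory.safe_plan is None:
                state.memory.safe_plan = executed_plan
            else:
                old = np.array(state.memory.safe_plan.via_x)
                new = np.array(executed_plan.via_x)
                blended = tuple(old + 0.3 * (new - old))
                state.memory.safe_plan = dataclasses.replace(
                    state.memory.safe_plan, via_x=blended
                )
        state.safety_bias = max(
            0.0, state.safety_bias - state.bias_decay_per_success
        )
        if state.success_count >= state.confidence_threshold:
            if not state.confidence_attained:
                state.confidence_attained = True
            state.mode = "efficient"
    else:
        state.mode = "safe"
        if state.memory.safe_plan is not None:
            # failure-driven plan correction: the remembered safe plan is
            # nudged away from the direction of the fall, so the memory
            # tracks the feasible band even as the internal model sharpens
            sign = 1.0 if outcome == "failure_backward" else -1.0
            old = np.array(state.memory.safe_plan.via_x)
            corrected = tuple(old + sign * np.array(PLAN_CORRECTION_STEP))
            state.memory.safe_plan = dataclasses.replace(
                state.memory.safe_plan, via_x=corrected
            )
            state.pending_reset = state.memory.safe_plan
            state.safety_bias = 0.1 if outcome == "failure_backward" else 0.0
        elif outcome == "failure_backward":
            state.safety_bias = min(1.0, state.safety_bias + state.bias_gain_per_failure)
        else:
            state.safety_bias = 0.5 * state.safety_bias
    return state
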