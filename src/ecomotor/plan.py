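"""Motor plans as three-via-point COM paths and a Gaussian plan policy.

A motor plan is a desired sagittal COM trajectory from the squat posture to
the standing posture.  Its spatial shape is a cubic-spline path x(y) through
three via points whose heights are fixed at 25/50/75 % of the COM rise; its
time course is a fixed rest-to-rest rise pacing (see ``_rise_profile``).
Only the horizontal (x) offsets of the via points are free, so the
reinforcement learner searches a 3-dimensional constrained box.  The policy
is a Gaussian over those offsets (exploration noise mostly shared along the
plan), updated by REINFORCE with an exponential-moving-average reward
baseline; the exploration scale is fixed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "MotorPlan",
    "PolicyDistribution",
    "PlanMemory",
    "sample_plan",
    "plan_from_offsets",
    "plan_to_reference",
    "policy_update",
]

#: heights of the three via points, as fractions of the COM rise
VIA_FRACTIONS = (0.25, 0.50, 0.75)

#: fractions of the movement duration spent smoothly ramping the rise speed
#: up from rest and back down to rest; the descent ramp is longer so the
#: vertical deceleration stays gentle while the pull is still fading
PACING_RAMP_UP = 0.28
PACING_RAMP_DOWN = 0.30


@dataclass(frozen=True)
class MotorPlan:
    """Desired COM trajectory: start/end points, via-point offsets, duration."""

    via_x: tuple[float, float, float]
    start: tuple[float, float]
    end: tuple[float, float]
    duration: float = 1.2

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not self.start[1] < self.end[1]:
            raise ValueError("start must lie below end")

    @property
    def via_points(self) -> list[tuple[float, float]]:
        rise = self.end[1] - self.start[1]
        return [
            (self.start[0] + vx, self.start[1] + f * rise)
            for vx, f in zip(self.via_x, VIA_FRACTIONS)
        ]


@dataclass
class PolicyDistribution:
    """Gaussian policy over via-point x offsets (REINFORCE with EMA baseline)."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(3))
    stdev: np.ndarray = field(default_factory=lambda: np.full(3, 0.005))
    learning_rate: float = 8e-6
    baseline: float = 0.0
    baseline_decay: float = 0.9
    baseline_initialized: bool = False
    #: constrained via-point search box (m, relative to the stance line),
    #: one (lo, hi) pair per via point; keeping the box tight is what makes
    #: the 3-parameter search tractable and is graded with height like the
    #: pull's tipping moment
    bounds: tuple = ((-0.02, 0.07), (-0.02, 0.10), (-0.02, 0.12))

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.stdev = np.asarray(self.stdev, dtype=float)
        if np.any(self.stdev <= 0):
            raise ValueError("stdev must be positive elementwise")

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean.tolist(),
                "stdev": self.stdev.tolist(),
                "learning_rate": self.learning_rate,
                "baseline": self.baseline,
                "baseline_decay": self.baseline_decay,
                "baseline_initialized": self.baseline_initialized,
                "bounds": np.asarray(self.bounds).tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "PolicyDistribution":
        d = json.loads(s)
        return cls(
            mean=np.array(d["mean"]),
            stdev=np.array(d["stdev"]),
            learning_rate=d["learning_rate"],
            baseline=d["baseline"],
            baseline_decay=d["baseline_decay"],
            baseline_initialized=d.get("baseline_initialized", False),
            bounds=tuple(map(tuple, d["bounds"]))
            if isinstance(d["bounds"][0], list)
            else tuple(d["bounds"]),
        )


@dataclass
class PlanMemory:
    """Plans that previously yielded a success in their condition."""

    safe_plan: MotorPlan | None = None
    unperturbed_plan: MotorPlan | None = None


def plan_from_offsets(
    offsets,
    start: tuple[float, float],
    end: tuple[float, float],
    duration: float = 1.2,
    bounds: tuple = ((-0.02, 0.07), (-0.02, 0.10), (-0.02, 0.12)),
) -> MotorPlan:
    """Build a plan from via-point x offsets, clipped to the search bounds.

    The path terminates still carrying most of the top via's lateral offset:
    the recorded stand-up ends at full height with a residual lean (settling
    back to quiet stance happens after the trial), so the final approach
    needs almost no horizontal braking while the pull is fading.
    """
    lo, hi = _bounds_arrays(bounds)
    clipped = tuple(float(v) for v in np.clip(np.asarray(offsets, float), lo, hi))
    end_leaned = (end[0] + END_LEAN_FRACTION * clipped[2], end[1])
    return MotorPlan(via_x=clipped, start=start, end=end_leaned, duration=duration)


#: hard-wired safe posture shape the sampling centre is pulled toward under
#: safety bias.  Graded with height — the pull's tipping moment grows with
#: the COM height, so a safe stand-up leans progressively further forward
#: as it rises and finishes the trial still leaned.
SAFE_SHAPE = (0.05, 0.09, 0.10)

#: fraction of the top via's lateral offset still held at the end of the
#: recorded movement
END_LEAN_FRACTION = 0.7

#: fraction of the exploration variance shared by all three via points
NOISE_COMMON_FRACTION = 0.8


def _bounds_arrays(bounds) -> tuple[np.ndarray, np.ndarray]:
    """Accept either a shared (lo, hi) pair or one pair per via point."""
    b = np.asarray(bounds, dtype=float)
    if b.shape == (2,):
        return np.full(3, b[0]), np.full(3, b[1])
    if b.shape == (3, 2):
        return b[:, 0], b[:, 1]
    raise ValueError("bounds must be (lo, hi) or three (lo, hi) pairs")


def sample_plan(
    policy: PolicyDistribution,
    rng: np.random.Generator | int,
    safety_bias: float = 0.0,
    safe_shape: tuple[float, float, float] = SAFE_SHAPE,
    start: tuple[float, float] = (0.05, 0.55),
    end: tuple[float, float] = (0.05, 1.05),
    duration: float = 1.2,
) -> MotorPlan:
    """Draw a plan from the policy, biased toward the safe posture shape.

    ``safety_bias`` in [0, 1] interpolates the sampling centre from the
    policy mean toward ``safe_shape`` (full bias centres the draw on the
    safe shape no matter where the mean has wandered); draws are clipped to
    the via-point bounds.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    shape = np.asarray(safe_shape, dtype=float)
    centre = policy.mean + safety_bias * (shape - policy.mean)
    # exploration noise is mostly shared along the plan: independent via
    # jitter would put high-curvature wiggles into the path spline (violent
    # lateral accelerations no motor system would emit), so a common
    # component dominates and per-via residuals stay small
    w = NOISE_COMMON_FRACTION
    z = (
        np.sqrt(w) * rng.standard_normal()
        + np.sqrt(1.0 - w) * rng.standard_normal(3)
    )
    draw = centre + policy.stdev * z
    return plan_from_offsets(
        draw, start=start, end=end, duration=duration, bounds=policy.bounds
    )


def _path_spline(plan: MotorPlan) -> CubicSpline:
    """Spatial path x(y): natural cubic spline through start, vias, end.

    Because the plan is a path in space, the via points lie on the executed
    trajectory exactly; the time course comes from the rise pacing below.
    """
    ys = np.array(
        [plan.start[1], *[p[1] for p in plan.via_points], plan.end[1]]
    )
    xs = np.array(
        [plan.start[0], *[p[0] for p in plan.via_points], plan.end[0]]
    )
    return CubicSpline(ys, xs, bc_type="natural")


def _rise_profile(t: np.ndarray, plan: MotorPlan) -> tuple[np.ndarray, ...]:
    """Fixed rest-to-rest rise pacing y(t), ydot(t), yddot(t).

    The squared height is driven linearly through a smooth trapezoidal speed
    profile (cosine ramps), i.e. ydot ~ 1/y through the steady phase: rising
    fast while the COM is low and slowly while it is high equalizes the
    velocity-proportional pull's tipping moment, which grows with both the
    vertical speed and the COM height.
    """
    D = plan.duration
    y0, y1 = plan.start[1], plan.end[1]
    A = y1**2 - y0**2
    tau = np.clip(t / D, 0.0, 1.0)
    ru, rd = PACING_RAMP_UP, PACING_RAMP_DOWN
    v = 1.0 / (1.0 - 0.5 * (ru + rd))
    s = np.empty_like(tau)
    sd = np.empty_like(tau)
    sdd = np.empty_like(tau)
    up = tau < ru
    down = tau > 1.0 - rd
    mid = ~(up | down)
    # cosine ramp up: sd = v*(1-cos(pi*tau/ru))/2
    sd[up] = v * 0.5 * (1 - np.cos(np.pi * tau[up] / ru))
    s[up] = v * 0.5 * (tau[up] - ru / np.pi * np.sin(np.pi * tau[up] / ru))
    sdd[up] = v * 0.5 * np.pi / ru * np.sin(np.pi * tau[up] / ru)
    sd[mid] = v
    s[mid] = v * 0.5 * ru + v * (tau[mid] - ru)
    sdd[mid] = 0.0
    tt = 1.0 - tau[down]
    sd[down] = v * 0.5 * (1 - np.cos(np.pi * tt / rd))
    s[down] = 1.0 - (v * 0.5 * (tt - rd / np.pi * np.sin(np.pi * tt / rd)))
    sdd[down] = -v * 0.5 * np.pi / rd * np.sin(np.pi * tt / rd)
    y = np.sqrt(y0**2 + A * s)
    yd = A * sd / (2 * y * D)
    ydd = A * sdd / (2 * y * D**2) - (A * sd) ** 2 / (4 * y**3 * D**2)
    return y, yd, ydd


def plan_to_reference(plan: MotorPlan, dt: float) -> np.ndarray:
    """Sample the planned COM trajectory and its analytic derivatives.

    The path spline x(y) is composed with the fixed rise pacing y(t); first
    and second time derivatives follow by the chain rule.  Returns an array
    of shape (n, 7) with columns (t, x, y, x_dot, y_dot, x_ddot, y_ddot).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    sx = _path_spline(plan)
    n = int(round(plan.duration / dt)) + 1
    t = np.linspace(0.0, plan.duration, n)
    y, yd, ydd = _rise_profile(t, plan)
    x = sx(y)
    dx = sx(y, 1)
    ddx = sx(y, 2)
    return np.column_stack(
        [t, x, y, dx * yd, yd, ddx * yd**2 + dx * ydd, ydd]
    )


def policy_update(
    policy: PolicyDistribution, executed_plan: MotorPlan, reward: float
) -> PolicyDistribution:
    """REINFORCE update of the policy mean; stdev is held fixed.

    mean <- mean + alpha * (reward - baseline) * (a - mean) / stdev^2,
    clipped to the via-point bounds; the baseline is an exponential moving
    average of past rewards.  The very first reward only seeds the baseline
    (an advantage against an arbitrary initial baseline would kick the mean
    in a random direction).
    """
    if not math.isfinite(reward):
        raise ValueError("reward must be finite")
    out = replace(policy)
    if not policy.baseline_initialized:
        out.baseline = reward
        out.baseline_initialized = True
        return out
    a = np.asarray(executed_plan.via_x, dtype=float)
    advantage = reward - policy.baseline
    grad = (a - policy.mean) / policy.stdev**2
    lo, hi = _bounds_arrays(policy.bounds)
    out.mean = np.clip(
        policy.mean + policy.learning_rate * advantage * grad, lo, hi
    )
    out.baseline = (
        policy.baseline_decay * policy.baseline
        + (1 - policy.baseline_decay) * reward
    )
    return out
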