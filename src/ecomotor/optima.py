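"""Point-mass optimal stand-up trajectories: maximal safety vs minimal energy.

A direct-collocation nonlinear program over the sagittal COM path of a point
mass rising from squat to stand in fixed time under the velocity-
proportional backward pull.  Two objectives are provided: *max_safety*
keeps the centre of pressure (COP) as far forward as possible (postural
stability against the backward pull), *min_energy* minimises the squared
actuator force integral.  The safety-optimal trajectory arches forward —
larger Trajectory Area and Initial Trajectory Area — whereas the energy-
optimal trajectory stays nearly straight and rises with a higher vertical
velocity peak, hence a larger peak pull.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["OptimizationSpec", "OptimalTrajectory", "solve_optimal_trajectory"]


@dataclass(frozen=True)
class OptimizationSpec:
    objective: str  # {"max_safety", "min_energy"}
    n_nodes: int = 40
    duration: float = 1.2
    mass: float = 77.0
    gravity: float = 9.81
    perturbation_gain_K: float = 3.0
    y_squat: float = 0.55
    y_stand: float = 1.05
    x_start: float = 0.05
    cop_bounds: tuple[float, float] = (-0.08, 0.17)
    x_bounds: tuple[float, float] = (-0.08, 0.17)

    def __post_init__(self):
        if self.objective not in ("max_safety", "min_energy"):
            raise ValueError("objective must be 'max_safety' or 'min_energy'")
        if self.n_nodes < 5:
            raise ValueError("need at least 5 collocation nodes")


@dataclass
class OptimalTrajectory:
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cop: np.ndarray
    pull: np.ndarray  # backward pull force magnitude, N
    objective_value: float
    converged: bool
    effort: float = field(default=np.nan)


def _kinematics(z: np.ndarray, spec: OptimizationSpec):
    """Decision variables are interior node positions; finite differences."""
    n = spec.n_nodes
    x = np.empty(n)
    y = np.empty(n)
    x[0], x[-1] = spec.x_start, spec.x_start + z[-1]  # free end lean
    y[0], y[-1] = spec.y_squat, spec.y_stand
    x[1:-1] = z[: n - 2]
    y[1:-1] = z[n - 2 : 2 * (n - 2)]
    dt = spec.duration / (n - 1)
    vx = np.gradient(x, dt)
    vy = np.gradient(y, dt)
    ax = np.gradient(vx, dt)
    ay = np.gradient(vy, dt)
    return x, y, vx, vy, ax, ay, dt


def _forces(x, y, vx, vy, ax, ay, spec: OptimizationSpec):
    m, g, K = spec.mass, spec.gravity, spec.perturbation_gain_K
    pull = K * m * np.maximum(vy, 0.0)
    fx = m * ax + pull  # actuator horizontal force
    fy = m * (ay + g)
    cop = x - y * (m * ax + pull) / np.maximum(m * (ay + g), 1e-3)
    return fx, fy, cop, pull


def solve_optimal_trajectory(spec: OptimizationSpec) -> OptimalTrajectory:
    """Direct collocation with penalty terms for bounds and rest boundaries."""
    n = spec.n_nodes
    tau = np.linspace(0, 1, n)
    y_init = spec.y_squat + (spec.y_stand - spec.y_squat) * (
        3 * tau**2 - 2 * tau**3
    )
    # warm start: a forward bow for the safety objective, straight otherwise
    bow = 0.08 if spec.objective == "max_safety" else 0.0
    x_init = spec.x_start + 4 * bow * tau * (1 - tau)
    z0 = np.concatenate([x_init[1:-1], y_init[1:-1], [bow * 0.5]])
    f_scale = spec.mass * spec.gravity

    def objective(z):
        x, y, vx, vy, ax, ay, dt = _kinematics(z, spec)
        fx, fy, cop, pull = _forces(x, y, vx, vy, ax, ay, spec)
        effort = np.sum((fx / f_scale) ** 2 + (fy / f_scale - 1.0) ** 2) * dt
        # soft constraints
        pen = 0.0
        pen += np.sum(np.clip(spec.cop_bounds[0] - cop, 0, None) ** 2)
        pen += np.sum(np.clip(cop - spec.cop_bounds[1], 0, None) ** 2)
        pen += np.sum(np.clip(spec.x_bounds[0] - x, 0, None) ** 2)
        pen += np.sum(np.clip(x - spec.x_bounds[1], 0, None) ** 2)
        pen += np.sum(np.clip(-np.diff(y), 0, None) ** 2)  # monotone rise
        pen += vx[0] ** 2 + vy[0] ** 2 + vx[-1] ** 2 + vy[-1] ** 2  # rest ends
        if spec.objective == "min_energy":
            core = effort
        else:
            # keep the COP as far forward as possible over the movement and
            # avoid provoking the velocity-proportional pull (low, even
            # vertical speed); a touch of effort for regularity
            core = (
                np.mean((spec.cop_bounds[1] - cop) ** 2)
                + 0.05 * np.mean((pull / (0.15 * f_scale)) ** 4)
                + 0.01 * effort
            )
        return core + 200.0 * pen

    res = minimize(
        objective, z0, method="L-BFGS-B",
        options=dict(maxiter=10000, maxfun=200000, ftol=1e-14, gtol=1e-10),
    )
    x, y, vx, vy, ax, ay, dt = _kinematics(res.x, spec)
    fx, fy, cop, pull = _forces(x, y, vx, vy, ax, ay, spec)
    effort = float(np.sum((fx / f_scale) ** 2 + (fy / f_scale - 1.0) ** 2) * dt)
    return OptimalTrajectory(
        t=tau * spec.duration, x=x, y=y, cop=cop, pull=pull,
        objective_value=float(res.fun), converged=bool(res.success),
        effort=effort,
    )
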