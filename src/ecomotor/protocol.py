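"""Experimental protocol orchestration for simulated participants.

One simulated experiment mirrors the human paradigm: a baseline block of 15
unperturbed trials (which also stores the unperturbed plan memory), a
perturbation block that runs until 60 successes are accumulated (bounded by
``max_perturbed_trials``), one unannounced catch trial with the pull turned
off, five further perturbed trials, and a de-adaptation block of 15
unperturbed trials for which the learner is told the pull is gone (the plan
is reset to the unperturbed memory and the internal-model correction is
partially shifted back toward the unperturbed dynamics).

Trial indices within the perturbation block can be normalized to a common
grid of 84 trials, matching the between-participant normalization used for
learning-curve averaging.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .body import BodyParams, classify_outcome, default_body, trajectory_to_frame
from .control import execute_trial
from .ecological import (
    EcologicalState,
    RewardSpec,
    compose_reward,
    draw_confidence_threshold,
    effort_cost,
    safety_cost,
    transition,
)
from .feedback import FeedbackGains
from .internal_model import InternalDynamicsModel, shift_toward_unperturbed
from .metrics import MetricSet, compute_metrics
from .plan import (
    MotorPlan,
    PolicyDistribution,
    plan_from_offsets,
    policy_update,
    sample_plan,
)

__all__ = [
    "ProtocolConfig",
    "TrialRecord",
    "RunResult",
    "PopulationSummary",
    "run_experiment",
    "run_population",
    "normalize_trial_index",
]


@dataclass(frozen=True)
class ProtocolConfig:
    n_baseline: int = 15
    required_successes: int = 60
    n_post_catch_perturbed: int = 5
    n_deadaptation: int = 15
    max_perturbed_trials: int = 300
    normalization_target: int = 84
    rng_seed: int = 0
    deadaptation_shift_rho: float = 0.1
    keep_trajectories: bool = True

    def __post_init__(self):
        for name in (
            "n_baseline",
            "required_successes",
            "n_post_catch_perturbed",
            "n_deadaptation",
            "max_perturbed_trials",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class TrialRecord:
    index: int
    block: str  # {baseline, perturbed, catch, post_catch, deadaptation}
    outcome: str
    plan: MotorPlan
    mode: str
    reward: float
    metrics: MetricSet
    feedback_multiplier_mean: float
    trajectory: list | None = None


@dataclass
class RunResult:
    trials: list[TrialRecord]
    completed: bool
    n_failures: int
    first_success_trial: int | None
    seed: int
    confidence_threshold: int = 0

    def block(self, name: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.block == name]

    @property
    def n_perturbed(self) -> int:
        return len(self.block("perturbed"))


def normalize_trial_index(
    trial_number: int, n_perturbed: int, target: int = 84
) -> float:
    """Map a 1-based perturbed-trial number onto the common 84-trial grid."""
    if n_perturbed <= 0:
        raise ValueError("n_perturbed must be positive")
    if not 1 <= trial_number <= n_perturbed:
        raise ValueError("trial_number out of range")
    return (trial_number / n_perturbed) * target


def _record(
    index: int,
    block: str,
    plan: MotorPlan,
    result,
    outcome: str,
    mode: str,
    reward: float,
    keep_traj: bool,
) -> TrialRecord:
    return TrialRecord(
        index=index,
        block=block,
        outcome=outcome,
        plan=plan,
        mode=mode,
        reward=reward,
        metrics=compute_metrics(result.trajectory),
        feedback_multiplier_mean=result.feedback_multiplier_mean,
        trajectory=result.trajectory if keep_traj else None,
    )


def run_experiment(
    config: ProtocolConfig,
    body: BodyParams | None = None,
    policy: PolicyDistribution | None = None,
    gains: FeedbackGains | None = None,
    reward_spec: RewardSpec | None = None,
    rng: np.random.Generator | None = None,
) -> RunResult:
    """Execute the full paradigm for one simulated participant."""
    if body is None:
        body = default_body()
    if policy is None:
        policy = PolicyDistribution()
    if gains is None:
        gains = FeedbackGains()
    if reward_spec is None:
        reward_spec = RewardSpec()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    unperturbed = dataclasses.replace(body, perturbation_gain_K=0.0)
    model = InternalDynamicsModel(params=unperturbed)
    eco = EcologicalState(confidence_threshold=draw_confidence_threshold(rng))
    start = (body.stance_x, body.leg_length_squat)
    end = (body.stance_x, body.leg_length_stand)
    keep = config.keep_trajectories

    trials: list[TrialRecord] = []
    idx = 0

    def spec_for(mode: str) -> RewardSpec:
        return dataclasses.replace(
            reward_spec, active_cost="safety" if mode == "safe" else "effort"
        )

    def run_one(block: str, params: BodyParams, plan: MotorPlan, mode: str):
        nonlocal idx
        result = execute_trial(plan, params, model, gains)
        outcome = (
            classify_outcome(result.trajectory, params)
            if not result.diverged
            else "failure_backward"
        )
        rec_spec = spec_for(mode)
        reward = compose_reward(
            outcome,
            rec_spec,
            safety_cost(result, params),
            effort_cost(result),
        )
        idx += 1
        trials.append(
            _record(idx, block, plan, result, outcome, mode, reward, keep)
        )
        return outcome, reward

    # --- baseline: unperturbed, habitual stand-ups; stores the plan memory.
    # The policy is not updated here: the unperturbed movement is already
    # well learned, the block only exercises it (and seeds the memory).
    for _ in range(config.n_baseline):
        plan = sample_plan(policy, rng, start=start, end=end)
        outcome, reward = run_one("baseline", unperturbed, plan, "efficient")
        if outcome == "success":
            eco.memory.unperturbed_plan = plan

    # --- perturbation block: run until the required successes
    successes = 0
    first_success: int | None = None
    perturbed_count = 0
    while (
        successes < config.required_successes
        and perturbed_count < config.max_perturbed_trials
    ):
        perturbed_count += 1
        if eco.pending_reset is not None:
            policy.mean = np.array(eco.pending_reset.via_x)
            eco.pending_reset = None
        plan = sample_plan(
            policy, rng, safety_bias=eco.safety_bias, start=start, end=end
        )
        outcome, reward = run_one("perturbed", body, plan, eco.mode)
        # in safe mode the plan adapts on failures (restore + corrective
        # shift + bias), not on successes; gradient refinement of the mean
        # acts on failures and throughout the efficient mode
        if eco.mode == "efficient" or outcome != "success":
            policy = policy_update(policy, plan, reward)
        eco = transition(eco, outcome, plan)
        if outcome == "success":
            successes += 1
            if first_success is None:
                first_success = perturbed_count

    completed = successes >= config.required_successes

    # --- catch trial: pull silently off; learner state untouched beforehand
    plan = sample_plan(
        policy, rng, safety_bias=eco.safety_bias, start=start, end=end
    )
    outcome, reward = run_one("catch", unperturbed, plan, eco.mode)
    eco = transition(eco, outcome, plan)

    # --- five further perturbed trials
    for _ in range(config.n_post_catch_perturbed):
        if eco.pending_reset is not None:
            policy.mean = np.array(eco.pending_reset.via_x)
            eco.pending_reset = None
        plan = sample_plan(
            policy, rng, safety_bias=eco.safety_bias, start=start, end=end
        )
        outcome, reward = run_one("post_catch", body, plan, eco.mode)
        policy = policy_update(policy, plan, reward)
        eco = transition(eco, outcome, plan)

    # --- de-adaptation: announced; plan reset + partial internal-model shift
    if eco.memory.unperturbed_plan is not None:
        policy.mean = np.array(eco.memory.unperturbed_plan.via_x)
    shift_toward_unperturbed(model, config.deadaptation_shift_rho)
    eco.safety_bias = 0.0
    for _ in range(config.n_deadaptation):
        plan = sample_plan(policy, rng, start=start, end=end)
        outcome, reward = run_one("deadaptation", unperturbed, plan, "efficient")
        policy = policy_update(policy, plan, reward)

    n_failures = sum(
        1
        for t in trials
        if t.block in ("perturbed", "post_catch") and t.outcome != "success"
    )
    return RunResult(
        trials=trials,
        completed=completed,
        n_failures=n_failures,
        first_success_trial=first_success,
        seed=config.rng_seed,
        confidence_threshold=eco.confidence_threshold,
    )


@dataclass
class PopulationSummary:
    n_runs: int
    n_completed: int
    mean_failures: float
    sd_failures: float
    mean_first_success: float
    sd_first_success: float
    per_trial_metrics: pd.DataFrame = field(repr=False, default=None)

    def to_json(self) -> str:
        d = {
            k: (v if not isinstance(v, pd.DataFrame) else None)
            for k, v in dataclasses.asdict(self).items()
            if k != "per_trial_metrics"
        }
        return json.dumps(d, indent=2)


def _per_trial_table(runs: Sequence[RunResult], target: int) -> pd.DataFrame:
    """Average metrics per normalized trial-index bin over completed runs."""
    rows = []
    for run in runs:
        pert = run.block("perturbed")
        n = len(pert)
        for i, rec in enumerate(pert, start=1):
            rows.append(
                {
                    "bin": int(round(normalize_trial_index(i, n, target))),
                    "trajectory_area": rec.metrics.trajectory_area,
                    "initial_trajectory_area": rec.metrics.initial_trajectory_area,
                    "smoothness": rec.metrics.smoothness,
                    "feedback_multiplier": rec.feedback_multiplier_mean,
                    "failed": rec.outcome != "success",
                }
            )
    df = pd.DataFrame(rows)
    return df.groupby("bin").mean().reset_index()


def run_population(
    n_runs: int,
    base_seed: int = 0,
    config: ProtocolConfig | None = None,
    body: BodyParams | None = None,
) -> tuple[list[RunResult], PopulationSummary]:
    """Independent seeded runs plus population statistics.

    Population statistics follow the convention of the simulated cohort:
    runs that fail to complete the paradigm are excluded from the failure
    and first-success averages (but counted in ``n_runs``/``n_completed``).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if config is None:
        config = ProtocolConfig(keep_trajectories=False)
    runs = []
    for i in range(n_runs):
        seed = base_seed + i
        cfg = dataclasses.replace(config, rng_seed=seed)
        runs.append(run_experiment(cfg, body=body))
    done = [r for r in runs if r.completed]
    fails = np.array([r.n_failures for r in done], dtype=float)
    firsts = np.array(
        [r.first_success_trial for r in done if r.first_success_trial], dtype=float
    )
    summary = PopulationSummary(
        n_runs=n_runs,
        n_completed=len(done),
        mean_failures=float(fails.mean()) if len(fails) else float("nan"),
        sd_failures=float(fails.std(ddof=1)) if len(fails) > 1 else 0.0,
        mean_first_success=float(firsts.mean()) if len(firsts) else float("nan"),
        sd_first_success=float(firsts.std(ddof=1)) if len(firsts) > 1 else 0.0,
        per_trial_metrics=_per_trial_table(done, config.normalization_target),
    )
    return runs, summary


def save_run(run: RunResult, out_dir: str | Path) -> None:
    """Write per-trial CSV (+ trajectories if kept) and a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in run.trials:
        rows.append(
            {
                "index": t.index,
                "block": t.block,
                "outcome": t.outcome,
                "mode": t.mode,
                "reward": t.reward,
                "trajectory_area": t.metrics.trajectory_area,
                "initial_trajectory_area": t.metrics.initial_trajectory_area,
                "smoothness": t.metrics.smoothness,
                "forward_peak": t.metrics.forward_peak,
                "backward_peak": t.metrics.backward_peak,
                "feedback_multiplier_mean": t.feedback_multiplier_mean,
            }
        )
    pd.DataFrame(rows).to_csv(out / "trials.csv", index=False)
    if any(t.trajectory for t in run.trials):
        frames = []
        for t in run.trials:
            if t.trajectory:
                df = trajectory_to_frame(t.trajectory)
                df.insert(0, "trial", t.index)
                frames.append(df)
        pd.concat(frames).to_csv(out / "trajectories.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(
            {
                "completed": run.completed,
                "n_failures": run.n_failures,
                "first_success_trial": run.first_success_trial,
                "seed": run.seed,
                "confidence_threshold": run.confidence_threshold,
                "n_trials": len(run.trials),
            },
            indent=2,
        )
    )
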