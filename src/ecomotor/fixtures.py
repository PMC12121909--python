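"""Synthetic human-like trial series for testing the analysis stack.

Generates trial sequences with controlled statistical structure — near-
straight baseline-like trajectories, perturbation-bent adaptation
trajectories whose forward bow follows a prescribed exponential trend with
noise, sporadic failures with backward excursions, and noisy two-channel
antagonist EMG whose co-contraction is elevated on and right after failures.
Everything is seeded and satisfies the preconditions of the metrics
operations, so the metrics and statistics layers are testable without
running the body simulator (and without any recorded human data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .body import TrajectorySample, frame_to_trajectory, trajectory_to_frame
from .metrics import EmgChannels, compute_metrics
from .protocol import TrialRecord

__all__ = ["FixtureSpec", "make_trial_series", "write_fixture_csv", "read_fixture_csv"]

RISE = 0.5
DURATION = 1.2


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic trial-series generator.

    The forward bow amplitude of trial i follows a*exp(-i/b)+c centimetres
    (a negative for a rising adaptation curve) plus Gaussian noise; failures
    are drawn from the per-trial probability curve and get backward-shifted
    trajectories.
    """

    n_trials: int = 84
    bow_a: float = -6.0  # cm
    bow_b: float = 15.0  # trials
    bow_c: float = 6.0  # cm
    noise_sd: float = 0.5  # cm
    failure_probability_curve: np.ndarray | None = None
    emg_burst_amplitude: float = 1.0
    emg_fs: float = 1000.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.bow_b <= 0:
            raise ValueError("bow_b must be positive")
        if self.failure_probability_curve is not None:
            p = np.asarray(self.failure_probability_curve)
            if np.any((p < 0) | (p > 1)):
                raise ValueError("failure probabilities must lie in [0, 1]")


def _bowed_trajectory(
    bow_cm: float, n: int = 121, duration: float = DURATION
) -> list[TrajectorySample]:
    """Minimum-jerk vertical rise with a parabolic horizontal bow (cm)."""
    t = np.linspace(0.0, duration, n)
    tau = t / duration
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    y = RISE * s
    yd = RISE * (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / duration
    ydd = RISE * (60 * tau - 180 * tau**2 + 120 * tau**3) / duration**2
    d = bow_cm / 100.0
    x = 4 * d * (y / RISE) * (1 - y / RISE)
    dxdy = 4 * d * (1 - 2 * y / RISE) / RISE
    d2xdy2 = -8 * d / RISE**2
    xd = dxdy * yd
    xdd = d2xdy2 * yd**2 + dxdy * ydd
    return [
        TrajectorySample(
            x=float(x[i]), y=float(y[i]), x_dot=float(xd[i]), y_dot=float(yd[i]),
            x_ddot=float(xdd[i]), y_ddot=float(ydd[i]), zmp_x=float(x[i]),
            t=float(t[i]),
        )
        for i in range(n)
    ]


def _emg_pair(
    rng: np.random.Generator,
    coc_level: float,
    amplitude: float,
    fs: float,
    duration: float = DURATION,
) -> EmgChannels:
    """Noisy antagonist burst pair with a prescribed activity ratio."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    burst = np.exp(-0.5 * ((t - duration / 2) / (duration / 6)) ** 2)
    carrier_vm = rng.standard_normal(n)
    carrier_bf = rng.standard_normal(n)
    vm = amplitude * coc_level * burst * carrier_vm
    bf = amplitude * burst * carrier_bf
    return EmgChannels(vastus_medialis=vm, biceps_femoris=bf, fs=fs)


def make_trial_series(spec: FixtureSpec) -> list[TrialRecord]:
    """Generate a seeded, human-like adaptation trial series."""
    rng = np.random.default_rng(spec.rng_seed)
    i = np.arange(1, spec.n_trials + 1)
    bow_trend = spec.bow_a * np.exp(-i / spec.bow_b) + spec.bow_c
    if spec.failure_probability_curve is not None:
        pfail = np.asarray(spec.failure_probability_curve, dtype=float)
        if len(pfail) != spec.n_trials:
            raise ValueError("failure curve length must equal n_trials")
    else:
        pfail = np.clip(0.8 * np.exp(-i / 12.0) + 0.05, 0, 1)
    records = []
    prev_failed = False
    for k in range(spec.n_trials):
        failed = bool(rng.random() < pfail[k])
        bow = bow_trend[k] + spec.noise_sd * rng.standard_normal()
        if failed:
            bow = -abs(bow) - 2.0  # backward excursion
        traj = _bowed_trajectory(bow)
        coc = 2.0 if (failed or prev_failed) else 1.2
        emg = _emg_pair(rng, coc, spec.emg_burst_amplitude, spec.emg_fs)
        records.append(
            TrialRecord(
                index=k + 1,
                block="perturbed",
                outcome="failure_backward" if failed else "success",
                plan=None,
                mode="safe",
                reward=0.0 if failed else 1.0,
                metrics=compute_metrics(traj, emg),
                feedback_multiplier_mean=coc - 1.0,
                trajectory=traj,
            )
        )
        prev_failed = failed
    return records


def write_fixture_csv(series: Sequence[TrialRecord], path: str | Path) -> None:
    """Write a trial series in the long trajectory CSV dialect."""
    frames = []
    for rec in series:
        df = trajectory_to_frame(rec.trajectory)
        df.insert(0, "trial", rec.index)
        df.insert(1, "outcome", rec.outcome)
        frames.append(df)
    if frames:
        pd.concat(frames).to_csv(path, index=False)
    else:
        pd.DataFrame(
            columns=["trial", "outcome", "t", "x", "y", "x_dot", "y_dot",
                     "x_ddot", "y_ddot", "zmp_x", "force_prismatic",
                     "torque_ankle"]
        ).to_csv(path, index=False)


def read_fixture_csv(path: str | Path) -> list[TrialRecord]:
    """Round-trip reader: rebuilds TrialRecords with recomputed metrics."""
    df = pd.read_csv(path)
    records = []
    if df.empty:
        return records
    for trial, grp in df.groupby("trial", sort=True):
        traj = frame_to_trajectory(grp)
        records.append(
            TrialRecord(
                index=int(trial),
                block="perturbed",
                outcome=str(grp.outcome.iloc[0]),
                plan=None,
                mode="safe",
                reward=0.0,
                metrics=compute_metrics(traj),
                feedback_multiplier_mean=0.0,
                trajectory=traj,
            )
        )
    return records
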