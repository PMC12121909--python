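"""Adaptation measures computed from sagittal COM trajectories and EMG.

Four measures quantify adaptation of the squat-to-stand motion:

* **Trajectory Area (TA)** — signed path integral of the horizontal COM
  deviation from the straight vertical reference over the whole rise,
  A = integral x dy, positive forward (against the perturbation).  Reported
  in cm^2 on trajectories normalized to a 0.5 m rise.
* **Initial Trajectory Area (ITA)** — the same integral over the first 5 %
  of the rise (y_end = 2.5 cm after scaling); a proxy for the feed-forward
  plan before feedback can act.
* **Smoothness (SM)** — dimensionless squared jerk,
  (integral jerk^2 dt) * D^3 / v_mean^2; lower is smoother (720 for an ideal
  one-dimensional minimum-jerk profile).
* **Co-Contraction (COC)** — iEMG ratio of vastus medialis to biceps
  femoris: band-pass (zero-lag Butterworth), full-wave rectify, RMS
  envelope, integrate, divide.

Trajectories are first translated to start at the origin and scaled so the
total rise equals 0.5 m (isotropic: x is scaled by the same factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import butter, filtfilt, savgol_filter

from .body import TrajectorySample

__all__ = [
    "MetricSet",
    "EmgChannels",
    "normalize_trajectory",
    "trajectory_area",
    "initial_trajectory_area",
    "smoothness",
    "co_contraction",
    "peak_displacements",
    "compute_metrics",
]

RISE_NORM = 0.5  # m, normalized COM rise
ITA_Y_END = 0.025  # m, first 5 % of the normalized rise
M2_TO_CM2 = 1e4


@dataclass(frozen=True)
class MetricSet:
    trajectory_area: float  # cm^2
    initial_trajectory_area: float  # cm^2
    smoothness: float
    forward_peak: float  # cm
    backward_peak: float  # cm
    co_contraction: float | None = None


@dataclass(frozen=True)
class EmgChannels:
    """Two-channel thigh EMG (antagonist pair), arbitrary units."""

    vastus_medialis: np.ndarray
    biceps_femoris: np.ndarray
    fs: float = 1000.0

    def __post_init__(self):
        if len(self.vastus_medialis) != len(self.biceps_femoris):
            raise ValueError("EMG channels must have equal length")


def _xy(traj: Sequence[TrajectorySample]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([s.x for s in traj]),
        np.array([s.y for s in traj]),
    )


def normalize_trajectory(
    raw: Sequence[TrajectorySample],
) -> list[TrajectorySample]:
    """Translate to the origin and scale the rise to 0.5 m (isotropic)."""
    if len(raw) < 2:
        raise ValueError("need at least two samples")
    rise = raw[-1].y - raw[0].y
    if rise <= 0:
        raise ValueError("trajectory must rise overall")
    k = RISE_NORM / rise
    x0, y0 = raw[0].x, raw[0].y
    return [
        TrajectorySample(
            x=(s.x - x0) * k,
            y=(s.y - y0) * k,
            x_dot=s.x_dot * k,
            y_dot=s.y_dot * k,
            x_ddot=s.x_ddot * k,
            y_ddot=s.y_ddot * k,
            zmp_x=(s.zmp_x - x0) * k,
            t=s.t,
            force_prismatic=s.force_prismatic,
            torque_ankle=s.torque_ankle,
        )
        for s in raw
    ]


def trajectory_area(
    traj: Sequence[TrajectorySample], y_end: float = RISE_NORM
) -> float:
    """Signed integral of x dy from the start height up to ``y_end``, in cm^2.

    Integrates along the path by the trapezoid rule; the path is cut at the
    first crossing of ``y_end`` (linear interpolation at the cut).
    """
    if not 0 < y_end <= RISE_NORM + 1e-12:
        raise ValueError("y_end must lie in (0, 0.5]")
    x, y = _xy(traj)
    area = 0.0
    for i in range(len(x) - 1):
        y0, y1 = y[i], y[i + 1]
        x0, x1 = x[i], x[i + 1]
        if y0 >= y_end:
            continue
        if y1 > y_end:
            # interpolate the crossing point
            f = (y_end - y0) / (y1 - y0)
            x1 = x0 + f * (x1 - x0)
            y1 = y_end
        area += 0.5 * (x0 + x1) * (y1 - y0)
    return area * M2_TO_CM2


def initial_trajectory_area(traj: Sequence[TrajectorySample]) -> float:
    """Trajectory area over the first 5 % of the rise (y_end = 2.5 cm)."""
    return trajectory_area(traj, y_end=ITA_Y_END)


def smoothness(
    traj: Sequence[TrajectorySample],
    duration: float | None = None,
    v_mean: float | None = None,
    savgol_window: int = 11,
) -> float:
    """Dimensionless squared jerk of the COM path.

    Jerk is obtained by Savitzky-Golay smoothed triple differentiation of
    both position components; the squared magnitude is integrated over the
    trial and scaled by D^3 / v_mean^2.
    """
    if len(traj) < max(4, savgol_window):
        raise ValueError("too few samples for jerk estimation")
    t = np.array([s.t for s in traj])
    x, y = _xy(traj)
    dt = float(np.mean(np.diff(t)))
    if duration is None:
        duration = t[-1] - t[0]
    if v_mean is None:
        path = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
        v_mean = path / duration
    if v_mean <= 0:
        raise ValueError("v_mean must be positive")
    jx = savgol_filter(x, savgol_window, 5, deriv=3, delta=dt)
    jy = savgol_filter(y, savgol_window, 5, deriv=3, delta=dt)
    integral = float(np.trapezoid(jx**2 + jy**2, t))
    return integral * duration**3 / v_mean**2


def _rms_envelope(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    n = max(1, int(round(window_s * fs)))
    kernel = np.ones(n) / n
    return np.sqrt(np.convolve(x**2, kernel, mode="same"))


def co_contraction(
    emg: EmgChannels,
    band: tuple[float, float] = (20.0, 500.0),
    order: int = 4,
    rms_window_s: float = 0.050,
) -> float:
    """iEMG ratio vastus medialis / biceps femoris.

    Both channels are band-pass filtered with a zero-lag Butterworth filter
    (forward-backward), full-wave rectified, enveloped by a moving RMS
    window, and integrated; the quotient of the integrals is returned.  The
    upper band edge is capped just below Nyquist when the sampling rate makes
    the nominal 500 Hz edge degenerate.
    """
    nyq = emg.fs / 2.0
    hi = min(band[1], 0.999 * nyq)
    if hi <= band[0]:
        raise ValueError("invalid band for this sampling rate")
    b, a = butter(order, [band[0] / nyq, hi / nyq], btype="band")
    t = np.arange(len(emg.vastus_medialis)) / emg.fs
    integrals = []
    for ch in (emg.vastus_medialis, emg.biceps_femoris):
        filtered = filtfilt(b, a, np.asarray(ch, dtype=float))
        env = _rms_envelope(np.abs(filtered), emg.fs, rms_window_s)
        integrals.append(float(np.trapezoid(env, t)))
    if integrals[1] <= 0 or not math.isfinite(integrals[1]):
        raise ValueError("degenerate biceps femoris signal (zero integral)")
    return integrals[0] / integrals[1]


def peak_displacements(
    traj: Sequence[TrajectorySample],
) -> tuple[float, float]:
    """(max forward, max backward) horizontal COM displacement in cm."""
    x, _ = _xy(traj)
    return float(np.max(x) * 100.0), float(np.min(x) * 100.0)


def compute_metrics(
    raw: Sequence[TrajectorySample], emg: EmgChannels | None = None
) -> MetricSet:
    """Normalize a raw trial trajectory and compute the full measure set."""
    traj = normalize_trajectory(raw)
    fwd, bwd = peak_displacements(traj)
    return MetricSet(
        trajectory_area=trajectory_area(traj),
        initial_trajectory_area=initial_trajectory_area(traj),
        smoothness=smoothness(traj),
        forward_peak=fwd,
        backward_peak=bwd,
        co_contraction=co_contraction(emg) if emg is not None else None,
    )
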