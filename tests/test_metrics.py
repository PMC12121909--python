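import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import butter, filtfilt

from ecomotor.body import TrajectorySample
from ecomotor.metrics import (
    EmgChannels,
    co_contraction,
    initial_trajectory_area,
    normalize_trajectory,
    peak_displacements,
    smoothness,
    trajectory_area,
)


def path_trajectory(x_of_y, n=201, rise=0.5, duration=1.2):
    """Trajectory with a prescribed x(y) profile on a minimum-jerk rise."""
    t = np.linspace(0, duration, n)
    tau = t / duration
    y = rise * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    x = np.array([x_of_y(v) for v in y])
    return [
        TrajectorySample(x=float(x[i]), y=float(y[i]), x_dot=0, y_dot=0,
                         x_ddot=0, y_ddot=0, zmp_x=float(x[i]), t=float(t[i]))
        for i in range(n)
    ]


def minimum_jerk_1d(n=601, d=0.5, duration=1.2):
    """Vertical minimum-jerk rise: the classic smoothness reference motion."""
    t = np.linspace(0, duration, n)
    tau = t / duration
    y = d * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return [
        TrajectorySample(x=0.0, y=float(v), x_dot=0, y_dot=0, x_ddot=0,
                         y_ddot=0, zmp_x=0.0, t=float(ti))
        for ti, v in zip(t, y)
    ]


class TestNormalize:
    def test_idempotent_on_normalized_input(self):
        traj = path_trajectory(lambda y: 0.01 * y)
        once = normalize_trajectory(traj)
        twice = normalize_trajectory(once)
        assert np.allclose([s.x for s in twice], [s.x for s in once])
        assert np.allclose([s.y for s in twice], [s.y for s in once])

    def test_scales_one_metre_rise_by_half(self):
        traj = path_trajectory(lambda y: 0.1, rise=1.0)
        norm = normalize_trajectory(traj)
        assert norm[-1].y == pytest.approx(0.5)
        # isotropic: x offsets are scaled by the same factor
        assert norm[-1].x - norm[0].x == pytest.approx(0.0)
        assert max(abs(s.x) for s in norm) == pytest.approx(0.0, abs=1e-12)

    def test_straight_line_stays_straight(self):
        traj = path_trajectory(lambda y: 0.04 + 0.2 * y, rise=0.8)
        norm = normalize_trajectory(traj)
        x = np.array([s.x for s in norm])
        y = np.array([s.y for s in norm])
        resid = np.polyfit(y, x, 1, full=True)[1]
        assert float(resid[0]) < 1e-16

    def test_rejects_non_rising(self):
        traj = path_trajectory(lambda y: 0.0)
        flipped = list(reversed(traj))
        with pytest.raises(ValueError):
            normalize_trajectory(flipped)


class TestTrajectoryArea:
    def test_straight_vertical_is_zero(self):
        traj = normalize_trajectory(path_trajectory(lambda y: 0.0))
        assert trajectory_area(traj) == pytest.approx(0.0, abs=1e-12)

    def test_rectangle_closed_form(self):
        # constant 2 cm forward offset after the origin shift is created by
        # a step at the start; use x(y) = 0.02*(y>0) approximated by offset
        # relative to the start point: integral = 0.02 * 0.5 = 100 cm^2
        traj = path_trajectory(lambda y: 0.02 * np.clip(y / 1e-6, 0, 1))
        norm = normalize_trajectory(traj)
        assert trajectory_area(norm) == pytest.approx(100.0, rel=1e-3)

    def test_parabola_closed_form(self):
        # x(y) = 4 d y (0.5 - y)/0.25, d = 2 cm: area = (2/3) d 0.5 = 66.67 cm^2
        d = 0.02
        traj = path_trajectory(lambda y: 4 * d * y * (0.5 - y) / 0.25)
        norm = normalize_trajectory(traj)
        assert trajectory_area(norm) == pytest.approx(
            (2.0 / 3.0) * d * 0.5 * 1e4, rel=1e-3
        )

    def test_sign_flips_under_mirror(self):
        d = 0.02
        bow = path_trajectory(lambda y: 4 * d * y * (0.5 - y) / 0.25)
        mirrored = path_trajectory(lambda y: -4 * d * y * (0.5 - y) / 0.25)
        a = trajectory_area(normalize_trajectory(bow))
        b = trajectory_area(normalize_trajectory(mirrored))
        assert a == pytest.approx(-b, rel=1e-9)
        assert a > 0

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.floats(0.2, 5.0))
    def test_linear_in_horizontal_scale(self, scale):
        d = 0.01
        base = normalize_trajectory(
            path_trajectory(lambda y: 4 * d * y * (0.5 - y) / 0.25)
        )
        scaled = [
            TrajectorySample(x=s.x * scale, y=s.y, x_dot=0, y_dot=0, x_ddot=0,
                             y_ddot=0, zmp_x=s.zmp_x, t=s.t)
            for s in base
        ]
        assert trajectory_area(scaled) == pytest.approx(
            scale * trajectory_area(base), rel=1e-9
        )


class TestInitialTrajectoryArea:
    def test_straight_is_zero(self):
        traj = normalize_trajectory(path_trajectory(lambda y: 0.0))
        assert initial_trajectory_area(traj) == pytest.approx(0.0, abs=1e-12)

    def test_rectangle_closed_form(self):
        # constant 2 cm offset: 0.02 * 0.025 m^2 = 5 cm^2
        traj = path_trajectory(lambda y: 0.02 * np.clip(y / 1e-6, 0, 1))
        norm = normalize_trajectory(traj)
        assert initial_trajectory_area(norm) == pytest.approx(5.0, rel=1e-3)

    def test_equals_full_area_of_truncated_path(self):
        d = 0.02
        norm = normalize_trajectory(
            path_trajectory(lambda y: 4 * d * y * (0.5 - y) / 0.25, n=2001)
        )
        truncated = [s for s in norm if s.y <= 0.025 + 1e-12]
        # close the truncated path exactly at the 2.5 cm crossing
        a, b = norm[len(truncated) - 1], norm[len(truncated)]
        f = (0.025 - a.y) / (b.y - a.y)
        import dataclasses

        truncated.append(
            dataclasses.replace(a, x=a.x + f * (b.x - a.x), y=0.025)
        )
        assert initial_trajectory_area(norm) == pytest.approx(
            trajectory_area(truncated, y_end=0.025), rel=1e-6
        )

    def test_integration_bound_is_25_mm(self):
        from ecomotor.metrics import ITA_Y_END, RISE_NORM

        assert ITA_Y_END == 0.05 * RISE_NORM == 0.025


class TestSmoothness:
    def test_minimum_jerk_closed_form(self):
        # for any 1-D minimum-jerk profile the dimensionless squared jerk is
        # exactly 720 (integral of the quintic's squared jerk, normalized)
        traj = minimum_jerk_1d()
        d, D = 0.5, 1.2
        sm = smoothness(traj, duration=D, v_mean=d / D)
        assert sm == pytest.approx(720.0, rel=0.01)

    def test_noise_strictly_increases_jerk_cost(self):
        traj = minimum_jerk_1d()
        rng = np.random.default_rng(0)
        noisy = [
            TrajectorySample(x=s.x + 1e-4 * rng.standard_normal(), y=s.y,
                             x_dot=0, y_dot=0, x_ddot=0, y_ddot=0,
                             zmp_x=0.0, t=s.t)
            for s in traj
        ]
        assert smoothness(noisy, 1.2, 0.5 / 1.2) > smoothness(traj, 1.2, 0.5 / 1.2)

    def test_invariant_under_time_dilation(self):
        # D^3 / v_mean^2 normalization: rescaling time leaves SM unchanged
        for stretch in (0.5, 2.0):
            traj = minimum_jerk_1d(duration=1.2)
            slow = minimum_jerk_1d(duration=1.2 * stretch)
            sm1 = smoothness(traj, 1.2, 0.5 / 1.2)
            sm2 = smoothness(slow, 1.2 * stretch, 0.5 / (1.2 * stretch))
            assert sm2 == pytest.approx(sm1, rel=1e-6)

    def test_translation_invariance(self):
        traj = minimum_jerk_1d()
        shifted = [
            TrajectorySample(x=s.x + 1.0, y=s.y + 2.0, x_dot=0, y_dot=0,
                             x_ddot=0, y_ddot=0, zmp_x=0.0, t=s.t)
            for s in traj
        ]
        assert smoothness(shifted, 1.2, 0.5 / 1.2) == pytest.approx(
            smoothness(traj, 1.2, 0.5 / 1.2)
        )


def synthetic_burst(fs=1000.0, duration=1.2, freq=80.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    envelope = np.exp(-0.5 * ((t - 0.6) / 0.15) ** 2)
    return amp * envelope * np.sin(2 * np.pi * freq * t)


class TestCoContraction:
    def test_identical_channels_give_unity(self):
        s = synthetic_burst()
        assert co_contraction(EmgChannels(s, s.copy())) == pytest.approx(1.0)

    def test_doubled_agonist_gives_two(self):
        s = synthetic_burst()
        assert co_contraction(EmgChannels(2 * s, s.copy())) == pytest.approx(2.0)

    def test_matches_analytic_envelope_ratio(self):
        # two in-band sinusoid bursts with known envelope amplitude ratio
        vm = synthetic_burst(freq=90.0, amp=1.7)
        bf = synthetic_burst(freq=90.0, amp=1.0)
        assert co_contraction(EmgChannels(vm, bf)) == pytest.approx(1.7, rel=0.02)

    def test_zero_phase_filtering(self):
        # forward-backward filtering leaves a symmetric pulse symmetric
        n = 4001
        x = np.zeros(n)
        x[n // 2] = 1.0
        b, a = butter(4, [20 / 500.0 * 0.999, 0.998], btype="band")
        y = filtfilt(b, a, x)
        # no group delay: the response peaks exactly at the impulse...
        assert np.argmax(np.abs(y)) == n // 2
        # ...and is symmetric about it (away from the padded edges)
        core = y[1000:3001]
        assert np.allclose(core, core[::-1], atol=1e-5 * np.max(np.abs(y)))

    def test_degenerate_denominator_rejected(self):
        vm = synthetic_burst()
        bf = np.zeros_like(vm)
        with pytest.raises(ValueError):
            co_contraction(EmgChannels(vm, bf))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            EmgChannels(np.zeros(10), np.zeros(11))


class TestPeakDisplacements:
    def test_straight_line_has_no_peaks(self):
        traj = normalize_trajectory(path_trajectory(lambda y: 0.0))
        assert peak_displacements(traj) == (0.0, 0.0)

    def test_bow_signs(self):
        traj = normalize_trajectory(
            path_trajectory(lambda y: 0.03 * np.sin(2 * np.pi * y / 0.5))
        )
        fwd, bwd = peak_displacements(traj)
        assert fwd > 0 > bwd

    def test_matches_stored_extrema(self):
        traj = normalize_trajectory(
            path_trajectory(lambda y: 0.02 * np.sin(2 * np.pi * y / 0.5))
        )
        x = [s.x for s in traj]
        fwd, bwd = peak_displacements(traj)
        assert fwd == pytest.approx(max(x) * 100)
        assert bwd == pytest.approx(min(x) * 100)
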