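import math

import numpy as np
import pytest
from scipy import integrate

from spiraldst import (
    InsufficientCoverageError,
    PressureModel,
    UndefinedAngleError,
    assign_spiral_angles,
    pen_pressure_score,
    score_trace,
    spiral_deviation,
    total_time,
)
from spiraldst.spiral import radius_at_angle

from conftest import polar_trace, template_trace


def unwrap_oracle(trace, spiral):
    """Brute-force reference: accumulate wrapped atan2 differences sample by
    sample, clamp backtracking to the running maximum and clamp at the sweep
    end.  Pure-python loop, independent of the vectorized implementation."""
    angles = []
    prev_raw = None
    current = spiral.start_angle_deg
    running_max = current
    for s in trace.samples:
        raw = math.degrees(
            math.atan2(spiral.center_y_px - s.y_px, s.x_px - spiral.center_x_px)
        )
        if prev_raw is not None:
            d = raw - prev_raw
            while d <= -180.0:
                d += 360.0
            while d > 180.0:
                d -= 360.0
            current += d
        prev_raw = raw
        running_max = max(running_max, current)
        angles.append(min(running_max, spiral.end_angle_deg))
    return np.array(angles)


def offset_trace(spiral, offset_px, n):
    angles = np.linspace(spiral.start_angle_deg, spiral.end_angle_deg, n)
    return polar_trace(spiral, angles, spiral.radius_at_angle(angles) + offset_px)


def offset_area_exact(spiral, offset_px):
    """Closed form: area between r(theta) and r(theta)+c is
    integral of (c*r + c^2/2) d(theta)."""
    sweep = np.deg2rad(spiral.sweep_deg)
    mean_r = (spiral.inner_radius_px + spiral.outer_radius_px) / 2.0
    return offset_px * mean_r * sweep + 0.5 * offset_px**2 * sweep


class TestAngleAssignment:
    def test_template_replay_recovers_generating_angles(self, spiral):
        n = 100
        trace = template_trace(spiral, n=n)
        profile = assign_spiral_angles(trace, spiral)
        expected = np.linspace(90, 810, n)
        assert np.allclose(profile.angle_deg, expected, atol=1e-6)
        assert np.allclose(profile.r_drawn_px, profile.r_ref_px, atol=1e-9)

    def test_quarter_turns_on_a_circle(self, spiral):
        # screen-up, screen-left, screen-down, screen-right is counterclockwise
        # in the y-up frame: 90, 180, 270, 360
        trace = polar_trace(spiral, [90, 180, 270, 360], 100.0)
        profile = assign_spiral_angles(trace, spiral)
        assert np.allclose(profile.angle_deg, [90, 180, 270, 360])

    def test_matches_bruteforce_oracle_on_random_walks(self, spiral):
        rng = np.random.default_rng(1234)
        for _ in range(20):
            steps = rng.uniform(-60.0, 100.0, size=500)
            angles = 90.0 + np.concatenate([[0.0], np.cumsum(steps)])
            radii = rng.uniform(30.0, 330.0, size=501)
            trace = polar_trace(spiral, angles, radii)
            profile = assign_spiral_angles(trace, spiral)
            assert np.allclose(profile.angle_deg, unwrap_oracle(trace, spiral), atol=1e-6)

    def test_backtracking_clamped_to_running_maximum(self, spiral):
        trace = polar_trace(spiral, [90, 150, 120, 100, 200], 100.0)
        profile = assign_spiral_angles(trace, spiral)
        assert np.allclose(profile.angle_deg, [90, 150, 150, 150, 200])
        assert np.all(np.diff(profile.angle_deg) >= 0)

    def test_angles_clamped_at_sweep_end(self, spiral):
        angles = np.linspace(90, 900, 300)  # keeps circling past 810
        trace = polar_trace(spiral, angles, 200.0)
        profile = assign_spiral_angles(trace, spiral)
        assert profile.angle_deg.max() == pytest.approx(810.0)

    def test_center_sample_rejected(self, spiral):
        trace = polar_trace(spiral, [90, 180, 270], [100.0, 0.0, 100.0])
        with pytest.raises(UndefinedAngleError):
            assign_spiral_angles(trace, spiral)

    def test_insufficient_coverage_rejected(self, spiral):
        trace = polar_trace(spiral, [90, 92, 95], 100.0)
        with pytest.raises(InsufficientCoverageError):
            assign_spiral_angles(trace, spiral)


class TestSpiralDeviation:
    def test_zero_on_template(self, spiral):
        assert spiral_deviation(template_trace(spiral, 800), spiral) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_constant_offset_matches_closed_form(self, spiral):
        exact = offset_area_exact(spiral, 10.0) / (1280 * 800) * 10_000
        # independent numeric oracle for the same area
        b = (spiral.outer_radius_px - spiral.inner_radius_px) / np.deg2rad(720)
        num, _ = integrate.quad(
            lambda th: 10.0 * (20.0 + b * th) + 50.0, 0.0, np.deg2rad(720)
        )
        assert exact == pytest.approx(num / (1280 * 800) * 10_000, rel=1e-12)
        got = spiral_deviation(offset_trace(spiral, 10.0, 500), spiral)
        assert got == pytest.approx(exact, rel=5e-3)
        assert exact == pytest.approx(233.165, abs=0.01)

    def test_halving_screen_area_doubles_score(self, spiral):
        trace_big = offset_trace(spiral, 10.0, 600)
        # same samples, screen of twice the area
        angles = np.linspace(90, 810, 600)
        trace_double = polar_trace(
            spiral, angles, spiral.radius_at_angle(angles) + 10.0, screen=(2560, 800)
        )
        assert spiral_deviation(trace_big, spiral) == pytest.approx(
            2.0 * spiral_deviation(trace_double, spiral)
        )

    def test_invariant_to_temporal_resampling(self, spiral):
        # same geometric path sampled at different densities
        a = spiral_deviation(offset_trace(spiral, 10.0, 500), spiral)
        b = spiral_deviation(offset_trace(spiral, 10.0, 5000), spiral)
        assert a == pytest.approx(b, rel=5e-3)

    def test_quadrature_error_shrinks_when_samples_double(self, spiral):
        # smooth wiggly path with a known reference from adaptive quadrature
        b = (spiral.outer_radius_px - spiral.inner_radius_px) / np.deg2rad(720)

        def integrand(th):
            delta = 10.0 + 5.0 * np.sin(4.0 * th)
            r = 20.0 + b * th
            return delta * r + 0.5 * delta * delta

        ref_area, _ = integrate.quad(integrand, 0.0, np.deg2rad(720), limit=400)
        ref = ref_area / (1280 * 800) * 10_000

        def score_at(n):
            angles = np.linspace(90, 810, n)
            th = np.deg2rad(angles - 90)
            radii = spiral.radius_at_angle(angles) + 10.0 + 5.0 * np.sin(4.0 * th)
            return spiral_deviation(polar_trace(spiral, angles, radii), spiral)

        errs = [abs(score_at(n) - ref) for n in (500, 1000, 2000)]
        assert errs[1] <= 0.6 * errs[0]
        assert errs[2] <= 0.6 * errs[1]


class TestTotalTime:
    def test_arithmetic_on_timestamps(self, spiral):
        n = 100
        t = np.linspace(0, 12_730, n)
        trace = polar_trace(spiral, np.linspace(90, 810, n), 100.0, t_ms=t)
        assert total_time(trace) == pytest.approx(12.73)

    def test_translation_invariance(self, spiral):
        n = 50
        angles = np.linspace(90, 810, n)
        a = polar_trace(spiral, angles, 100.0, t_ms=np.linspace(500, 1500, n))
        assert total_time(a) == pytest.approx(1.0)


class TestPenPressure:
    def test_zero_when_at_or_below_typical_force(self, spiral):
        trace = template_trace(spiral, 200, pressure_n=1.45)
        assert pen_pressure_score(trace) == 0.0

    def test_single_hard_press(self, spiral):
        # stamp area 100 px at 1 N excess -> 100 N*px from that sample alone
        model = PressureModel(f_typ_n=1.45, stamp_base_px=1.0, stamp_gain_px_per_n=99.0)
        trace = polar_trace(spiral, [90, 180, 270], 100.0, pressure_n=[0.0, 2.45, 0.0])
        assert pen_pressure_score(trace, model) == pytest.approx(100.0 * (2.45 - 1.45))

    def test_matches_direct_sum_oracle_on_simulated_trace(self, spiral):
        from spiraldst import simulate_trace
        from spiraldst.simulate import PD_PROFILE

        rng = np.random.default_rng(99)
        params = PD_PROFILE.draw(rng, spiral.sweep_deg)
        trace = simulate_trace(spiral, params, rng=rng)
        model = PressureModel()
        expected = 0.0
        for s in trace.samples:  # independent scalar summation
            excess = max(0.0, s.pressure_n - model.f_typ_n)
            area = model.stamp_base_px + round(model.stamp_gain_px_per_n * excess)
            expected += area * excess
        assert pen_pressure_score(trace, model) == pytest.approx(expected, rel=1e-12)
        assert expected > 0

    def test_monotone_in_pressure(self, spiral):
        base = polar_trace(spiral, [90, 300, 500], 100.0, pressure_n=[1.5, 1.6, 1.7])
        bumped = polar_trace(spiral, [90, 300, 500], 100.0, pressure_n=[1.5, 1.9, 1.7])
        assert pen_pressure_score(bumped) >= pen_pressure_score(base)


class TestScoreTrace:
    def test_template_triple(self, spiral):
        trace = template_trace(spiral, 600, duration_s=12.73, pressure_n=1.0)
        triple = score_trace(trace, spiral)
        assert triple.sd_score == pytest.approx(0.0, abs=1e-9)
        assert triple.tt_s == pytest.approx(12.73)
        assert triple.pp_score == 0.0

    def test_deterministic(self, spiral):
        trace = offset_trace(spiral, 7.0, 400)
        assert score_trace(trace, spiral) == score_trace(trace, spiral)

    def test_pd_triple_dominates_healthy(self, spiral):
        from spiraldst import ProfileParams, simulate_trace

        healthy = ProfileParams(
            angular_speed_deg_s=720 / 12.0, radial_noise_sd_px=1.2,
            pressure_base_n=1.0, seed=5,
        )
        pd = ProfileParams(
            angular_speed_deg_s=720 / 20.0, tremor_amp_px=3.0, tremor_freq_hz=5.5,
            radial_noise_sd_px=2.0, pressure_base_n=1.45, pressure_excess_n=0.5,
            pressure_noise_sd_n=0.1, seed=6,
        )
        t_h = score_trace(simulate_trace(spiral, healthy), spiral)
        t_p = score_trace(simulate_trace(spiral, pd), spiral)
        assert t_p.sd_score > t_h.sd_score
        assert t_p.tt_s > t_h.tt_s
        assert t_p.pp_score > t_h.pp_score
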