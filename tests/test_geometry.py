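"""Targeting geometry: closest approach, engagement, the flagged metric D,
plane angulation and tip-to-wall distance, each against an independent oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from evdassess import (
    RAS,
    AnatomicalFrame,
    TargetSphere,
    Trajectory,
    angulation,
    closest_approach,
    engagement,
    line_distance,
    mdm,
    measure_trial,
    metric_D,
)
from evdassess.exceptions import DegenerateProjectionError, InvalidInputError


def brute_force_closest(traj, target, n=1_000_001):
    """Oracle: minimize point-to-center distance over a dense grid of the segment."""
    t = np.linspace(0.0, traj.depth, n)
    pts = traj.entry[None, :] + t[:, None] * traj.direction[None, :]
    return np.linalg.norm(pts - target.center, axis=1).min()


def sampled_engagement(traj, target, n=200_001):
    """Oracle: in-ball fraction of a dense sampling of the segment, times its length."""
    t = np.linspace(0.0, traj.depth, n)
    pts = traj.entry[None, :] + t[:, None] * traj.direction[None, :]
    inside = np.linalg.norm(pts - target.center, axis=1) <= target.radius
    return inside.mean() * traj.depth


class TestClosestApproach:
    def test_center_on_segment_gives_zero(self):
        traj = Trajectory(entry=[-30, 0, 0], direction=[1, 0, 0], depth=60)
        assert closest_approach(traj, TargetSphere([0, 0, 0], 10)) == pytest.approx(0.0)

    def test_tangent_line_gives_radius(self):
        traj = Trajectory(entry=[-50, 10, 0], direction=[1, 0, 0], depth=100)
        target = TargetSphere([0, 0, 0], 10)
        assert closest_approach(traj, target) == pytest.approx(10.0)

    def test_tip_clamped_case(self):
        # segment stops 4 mm short of the center; the frozen value 4 was
        # confirmed by brute-force minimization over 1e6 segment points
        traj = Trajectory(entry=[0, 0, 0], direction=[1, 0, 0], depth=1)
        target = TargetSphere([5, 0, 0], 1)
        assert closest_approach(traj, target) == pytest.approx(4.0)
        assert brute_force_closest(traj, target) == pytest.approx(4.0, abs=1e-6)

    def test_matches_brute_force_on_random_cases(self, rng):
        for _ in range(20):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            traj = Trajectory(entry=rng.uniform(-50, 50, 3), direction=direction,
                              depth=rng.uniform(10, 120))
            target = TargetSphere(rng.uniform(-50, 50, 3), rng.uniform(2, 25))
            d = closest_approach(traj, target)
            assert d == pytest.approx(brute_force_closest(traj, target, n=200_001), abs=1e-3)
            assert d >= line_distance(traj, target) - 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            Trajectory(entry=[0, 0, 0], direction=[1, 1, 0], depth=10)  # non-unit
        with pytest.raises(InvalidInputError):
            Trajectory(entry=[0, 0, 0], direction=[1, 0, 0], depth=0)
        with pytest.raises(InvalidInputError):
            TargetSphere([0, 0, 0], -1)


class TestEngagement:
    def test_diametral_traversal_is_full_diameter(self):
        traj = Trajectory(entry=[-40, 0, 0], direction=[1, 0, 0], depth=80)
        assert engagement(traj, TargetSphere([0, 0, 0], 10)) == pytest.approx(20.0)

    def test_tangent_gives_zero(self):
        traj = Trajectory(entry=[-40, 10, 0], direction=[1, 0, 0], depth=80)
        assert engagement(traj, TargetSphere([0, 0, 0], 10)) == pytest.approx(0.0)

    def test_offset_chord(self):
        # full traversal at line distance 3 of an R=5 ball: chord 2*sqrt(25-9) = 8,
        # confirmed by the dense-sampling oracle
        traj = Trajectory(entry=[-40, 3, 0], direction=[1, 0, 0], depth=80)
        target = TargetSphere([0, 0, 0], 5)
        assert engagement(traj, target) == pytest.approx(8.0)
        assert sampled_engagement(traj, target) == pytest.approx(8.0, abs=5e-3)

    def test_chord_identity_on_random_full_traversals(self, rng):
        # whenever the full chord is interior to the segment, R^2 = (E/2)^2 + d_line^2
        for _ in range(50):
            target = TargetSphere(rng.uniform(-20, 20, 3), rng.uniform(5, 20))
            d_line = rng.uniform(0, target.radius * 0.99)
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            perp = np.cross(axis, rng.standard_normal(3))
            perp /= np.linalg.norm(perp)
            entry = target.center + perp * d_line - axis * 100.0
            traj = Trajectory(entry=entry, direction=axis, depth=200.0)
            E = engagement(traj, target)
            assert (E / 2) ** 2 + d_line**2 == pytest.approx(target.radius**2, abs=1e-9)

    def test_matches_sampling_oracle_on_random_segments(self, rng):
        # includes partial entries, misses, and interior endpoints
        for _ in range(100):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            traj = Trajectory(entry=rng.uniform(-30, 30, 3), direction=direction,
                              depth=rng.uniform(5, 80))
            target = TargetSphere(rng.uniform(-30, 30, 3), rng.uniform(2, 20))
            assert engagement(traj, target) == pytest.approx(
                sampled_engagement(traj, target, n=100_001), abs=5e-3
            )

    def test_positive_engagement_implies_segment_reaches_inside(self, rng):
        for _ in range(50):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            traj = Trajectory(entry=rng.uniform(-30, 30, 3), direction=direction,
                              depth=rng.uniform(5, 80))
            target = TargetSphere(rng.uniform(-30, 30, 3), rng.uniform(2, 20))
            if engagement(traj, target) > 0:
                assert closest_approach(traj, target) < target.radius


class TestMetricD:
    def test_perfect_targeting(self):
        assert metric_D(0.0, 7.5).magnitude == pytest.approx(0.0)

    def test_wall_value_equals_radius(self):
        m = metric_D(1.0, 1.0)
        assert m.magnitude == pytest.approx(1.0)
        assert not m.outside

    def test_outside_branch_components(self):
        # |R - i sqrt(d^2-R^2)| with d=2, R=1: sqrt(1 + 3) = 2 (symbolic oracle)
        m = metric_D(2.0, 1.0)
        assert m.real_part == pytest.approx(1.0)
        assert abs(m.imag_part) == pytest.approx(math.sqrt(3.0))
        assert m.magnitude == pytest.approx(abs(complex(1.0, -math.sqrt(3.0))))
        assert m.outside

    def test_magnitude_equals_d_outside(self):
        for d in (1.0, 1.5, 3.0, 10.0, 100.0):
            assert metric_D(d, 1.0).magnitude == pytest.approx(d, abs=1e-12)

    @given(st.floats(0.0, 0.999999))
    @settings(max_examples=200, deadline=None)
    def test_lorentz_identity_inside(self, frac):
        R = 10.0
        d = frac * R
        D = metric_D(d, R).real_part
        assert 1.0 - D / R == pytest.approx(math.sqrt(1.0 - (d / R) ** 2), abs=1e-9)

    def test_continuity_at_wall(self):
        # |D(R-eps)| = R - sqrt(2R*eps - eps^2) and |D(R+eps)| = R + eps both -> R
        R = 4.0
        for eps in (1e-3, 1e-6, 1e-9):
            assert abs(metric_D(R - eps, R).magnitude - R) <= math.sqrt(2 * R * eps) + 1e-9
            assert abs(metric_D(R + eps, R).magnitude - R) <= eps + 1e-12

    @given(st.lists(st.floats(0.0, 50.0), min_size=2, max_size=30), st.floats(0.5, 20.0))
    @settings(max_examples=200, deadline=None)
    def test_magnitude_monotone_and_dominated_by_d(self, ds, R):
        ds = sorted(ds)
        mags = [metric_D(d, R).magnitude for d in ds]
        assert all(b >= a - 1e-12 for a, b in zip(mags, mags[1:]))
        assert all(m <= d + 1e-12 for m, d in zip(mags, ds))

    def test_flat_growth_near_center(self):
        # dD/dd -> 0 as d -> 0: central targeting errors barely move the metric
        R = 10.0
        h = 1e-5
        for d in (1e-4, 1e-3):
            deriv = (metric_D(d + h, R).magnitude - metric_D(d, R).magnitude) / h
            assert deriv < 5e-3

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            metric_D(-1.0, 5.0)
        with pytest.raises(InvalidInputError):
            metric_D(1.0, 0.0)


class TestAngulation:
    def test_identical_directions(self):
        traj = Trajectory([0, 0, 0], [0, 0.6, 0.8], 50)
        assert angulation(traj, traj) == pytest.approx((0.0, 0.0), abs=1e-6)

    def test_antipodal_directions(self):
        a = Trajectory([0, 0, 0], [0, 0.6, 0.8], 50)
        b = Trajectory([0, 0, 0], [0, -0.6, -0.8], 50)
        sag, cor = angulation(a, b)
        assert sag == pytest.approx(180.0, abs=1e-6)
        assert cor == pytest.approx(180.0, abs=1e-6)

    def test_rotation_about_sagittal_normal(self, rng):
        # rotating about the sagittal plane's normal changes the sagittal-plane
        # angle by exactly the rotation magnitude (rotation-matrix oracle)
        ideal_dir = np.array([0.0, 0.5, math.sqrt(0.75)])
        ideal = Trajectory([0, 0, 0], ideal_dir, 50)
        for angle in (1.0, 10.0, 45.0):
            rot = Rotation.from_rotvec(np.radians(angle) * np.array([1.0, 0.0, 0.0]))
            actual = Trajectory([0, 0, 0], rot.apply(ideal_dir), 50)
            sag, _ = angulation(actual, ideal)
            assert sag == pytest.approx(angle, abs=1e-6)

    def test_degenerate_projection_raises(self):
        # a direction along the sagittal normal has no sagittal-plane heading
        actual = Trajectory([0, 0, 0], [1, 0, 0], 50)
        ideal = Trajectory([0, 0, 0], [0, 1, 0], 50)
        with pytest.raises(DegenerateProjectionError):
            angulation(actual, ideal)

    def test_custom_frame(self):
        frame = AnatomicalFrame(sagittal_normal=[0, 0, 1], coronal_normal=[0, 1, 0])
        a = Trajectory([0, 0, 0], [1, 0, 0], 50)
        b = Trajectory([0, 0, 0], [0.6, 0.8, 0], 50)
        sag, cor = angulation(a, b, frame)
        assert sag == pytest.approx(math.degrees(math.atan2(0.8, 0.6)), abs=1e-6)
        assert cor == pytest.approx(0.0, abs=1e-6)


class TestMDM:
    @pytest.mark.parametrize(
        "tip,expected",
        [([0, 0, 0], -8.0), ([8, 0, 0], 0.0), ([16, 0, 0], 8.0)],
    )
    def test_signed_wall_distance(self, tip, expected):
        assert mdm(tip, TargetSphere([0, 0, 0], 8)) == pytest.approx(expected)


class TestMeasureTrial:
    def test_perfect_diametral_trial(self):
        R = 10.0
        direction = np.array([0.6, 0.8, 0.0])
        traj = Trajectory(-40 * direction, direction, 80)
        target = TargetSphere([0, 0, 0], R)
        m = measure_trial(traj, target, traj, task_time=30.0)
        assert m.engagement == pytest.approx(2 * R)
        assert m.closest_distance == pytest.approx(0.0)
        assert m.metric.magnitude == pytest.approx(0.0)
        assert (m.sagittal_angle, m.coronal_angle) == pytest.approx((0.0, 0.0), abs=1e-6)
        assert m.mdm == pytest.approx(np.linalg.norm(traj.tip) - R)
        assert m.task_time == 30.0

    def test_wide_miss(self):
        R = 5.0
        direction = np.array([0.6, 0.8, 0.0])
        # offset the whole path 3R perpendicular to its heading
        entry = np.array([0.0, 0.0, 3 * R]) - 40 * direction
        traj = Trajectory(entry, direction, 80)
        target = TargetSphere([0, 0, 0], R)
        ideal = Trajectory(entry, direction, 80)
        m = measure_trial(traj, target, ideal, task_time=12.0)
        assert m.engagement == pytest.approx(0.0)
        assert m.metric.outside
        assert m.metric.magnitude == pytest.approx(3 * R)

    def test_tip_short_trial_measures_to_tip(self):
        # clamped-segment oracle: stopping 4 mm before an R=1 target leaves d=4, E=0
        direction = np.array([0.6, 0.8, 0.0])
        traj = Trajectory([0, 0, 0], direction, 1)
        target = TargetSphere(5 * direction, 1)
        ideal = Trajectory([0, 0, 0], direction, 1)
        m = measure_trial(traj, target, ideal, task_time=5.0)
        assert m.engagement == pytest.approx(0.0)
        assert m.closest_distance == pytest.approx(4.0)
        assert m.metric.outside
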