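"""Speed, segmentation, jump extraction, selections and estimators."""

import math

import numpy as np
import pytest

from runtumble import (
    DataError,
    DomainConfig,
    DomainError,
    JumpEvent,
    SegmentationConfig,
    Trajectory,
    compute_speed,
    direction_histogram,
    estimate_kappa,
    extract_jumps,
    fit_directional_bias,
    fit_position_law,
    occupancy_distribution,
    segment_runs,
    select_center_window,
    select_perpendicular,
    trim_extremes,
)
from runtumble.binning import bin_positions


def make_jump(theta=0.0, length=10.0, start_x=50.0, start_y=30.0, start_time=0.0):
    return JumpEvent.from_endpoints(
        (start_x, start_y),
        (start_x + length * math.cos(theta), start_y + length * math.sin(theta)),
        start_time,
        start_time + 1.0,
    )


class TestComputeSpeed:
    def test_stationary(self):
        t = np.arange(10) / 30
        traj = Trajectory(t, np.full(10, 5.0), np.full(10, 5.0))
        assert np.all(compute_speed(traj) == 0)

    def test_constant_velocity(self):
        t = np.arange(10) / 30
        traj = Trajectory(t, 0.5 * np.arange(10), np.zeros(10))
        assert np.allclose(compute_speed(traj), 15.0)

    def test_non_uniform_spacing_rejected(self):
        t = np.array([0.0, 1 / 30, 2.5 / 30, 3 / 30])
        traj = Trajectory(t, np.zeros(4), np.zeros(4))
        with pytest.raises(DataError):
            compute_speed(traj)


class TestSegmentRuns:
    def test_single_run(self):
        runs = segment_runs([0, 0, 15, 20, 15, 0, 0], SegmentationConfig())
        assert runs == [(2, 5)]

    def test_all_below_threshold(self):
        assert segment_runs([1, 2, 3], SegmentationConfig()) == []

    def test_threshold_inclusive(self):
        assert segment_runs([0, 10.0, 0], SegmentationConfig()) == [(1, 2)]

    def test_min_run_frames(self):
        cfg = SegmentationConfig(min_run_frames=2)
        assert segment_runs([0, 15, 0, 15, 15, 0], cfg) == [(3, 5)]


class TestExtractJumps:
    def test_axis_aligned_jumps(self):
        t = np.arange(4) / 30
        traj = Trajectory(t, np.array([10.0, 13.0, 13.0, 13.0]), np.full(4, 5.0))
        jumps = extract_jumps(traj, [(0, 1)])
        assert len(jumps) == 1
        assert jumps[0].length == pytest.approx(3.0)
        assert jumps[0].theta == pytest.approx(0.0)

        traj = Trajectory(t, np.full(4, 10.0), np.array([5.0, 9.0, 9.0, 9.0]))
        (j,) = extract_jumps(traj, [(0, 1)])
        assert j.length == pytest.approx(4.0)
        assert j.theta == pytest.approx(math.pi / 2)

    def test_zero_displacement_run_dropped(self, caplog):
        t = np.arange(3) / 30
        traj = Trajectory(t, np.full(3, 1.0), np.full(3, 1.0))
        with caplog.at_level("WARNING"):
            jumps = extract_jumps(traj, [(0, 2)])
        assert jumps == []
        assert "zero-displacement" in caplog.text


class TestSelections:
    def test_perpendicular_window(self):
        def exact(theta):
            # set theta directly so the closed interval bounds are hit exactly
            j = make_jump(theta=theta)
            return JumpEvent(
                j.start_x, j.start_y, j.end_x, j.end_y, theta, j.length,
                j.start_time, j.end_time,
            )

        kept = select_perpendicular(
            [exact(t) for t in (math.pi / 2, 0.0, 3 * math.pi / 8, -5 * math.pi / 8, -math.pi / 2)]
        )
        # pi/2, both closed bounds and -pi/2 kept; the down-gradient jump dropped
        assert [j.theta for j in kept] == [
            math.pi / 2, 3 * math.pi / 8, -5 * math.pi / 8, -math.pi / 2
        ]

    def test_center_window_strict(self):
        jumps = [make_jump(start_x=x) for x in (45.0, 50.0, 55.0, 45.001)]
        kept = select_center_window(jumps)
        assert [j.start_x for j in kept] == [50.0, 45.001]

    def test_empty_input(self):
        assert select_center_window([]) == []


class TestTrimExtremes:
    def test_removes_two_largest_and_smallest(self):
        jumps = [make_jump(length=l, start_time=i) for i, l in enumerate([5, 7, 9, 11, 20, 25])]
        kept = trim_extremes(jumps)
        assert sorted(j.length for j in kept) == [7, 9, 11]

    def test_tie_broken_by_earliest_start(self):
        jumps = [
            make_jump(length=l, start_time=t)
            for l, t in [(1.0, 0.0), (1.0, 10.0), (2.0, 20.0), (3.0, 30.0), (4.0, 40.0)]
        ]
        kept = trim_extremes(jumps)
        lengths_times = {(j.length, j.start_time) for j in kept}
        # earliest of the tied minima was removed
        assert (1.0, 0.0) not in lengths_times
        assert (1.0, 10.0) in lengths_times

    def test_too_few_jumps_rejected(self):
        with pytest.raises(DataError):
            trim_extremes([make_jump()] * 3)


class TestFitPositionLaw:
    def test_exact_recovery_on_linear_data(self):
        rng = np.random.default_rng(1)
        jumps = [
            make_jump(length=0.063 * x + 12.9, start_x=x) for x in rng.uniform(0, 100, 40)
        ]
        est = fit_position_law(jumps)
        assert est.a_hat == pytest.approx(0.063, abs=1e-10)
        assert est.l0_hat == pytest.approx(12.9, abs=1e-8)

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(42)
        xs = rng.uniform(0, 100, 200)
        jumps = [
            make_jump(length=0.063 * x + 12.9 + rng.normal(0, 3.0), start_x=x) for x in xs
        ]
        est = fit_position_law(jumps)
        assert abs(est.a_hat - 0.063) < 3 * est.a_se

    def test_rank_condition(self):
        two_x = [make_jump(start_x=x, length=l) for x, l in [(10, 13), (20, 14), (20, 14.1)]]
        est = fit_position_law(two_x)
        assert est.n_used == 3
        same_x = [make_jump(start_x=10.0, length=l) for l in (13, 14, 15)]
        with pytest.raises(DataError):
            fit_position_law(same_x)


class TestFitDirectionalBias:
    def test_published_ratio(self):
        """The printed fit 3.85 cos(theta) + 13.1 implies b ~ 0.294."""
        assert 3.85 / 13.1 == pytest.approx(0.2939, abs=5e-4)

    def test_exact_recovery(self):
        thetas = np.linspace(-math.pi, math.pi, 24, endpoint=False)
        jumps = [make_jump(theta=t, length=13.1 * (1 + 0.295 * math.cos(t))) for t in thetas]
        est = fit_directional_bias(jumps)
        assert est.slope == pytest.approx(13.1 * 0.295, abs=1e-9)
        assert est.intercept == pytest.approx(13.1, abs=1e-9)
        assert est.b_hat == pytest.approx(0.295, abs=1e-10)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(2718)
        n = 10**4
        thetas = rng.uniform(-math.pi, math.pi, n)
        jumps = [
            make_jump(theta=t, length=13.1 * (1 + 0.295 * math.cos(t)) + rng.normal(0, 3))
            for t in thetas
        ]
        est = fit_directional_bias(jumps)
        assert abs(est.b_hat - 0.295) < 0.02
        assert est.b_se > 0

    def test_negative_intercept_rejected(self):
        # steep positive slope over cos(theta) in [0.8, 1] extrapolates to a
        # negative intercept at cos(theta) = 0
        jumps = [
            make_jump(theta=math.acos(0.8), length=0.1),
            make_jump(theta=math.acos(0.9), length=1.0),
            make_jump(theta=0.0, length=2.0),
        ]
        with pytest.raises(DataError):
            fit_directional_bias(jumps)


class TestEstimateKappa:
    def test_published_value(self):
        assert estimate_kappa(0.295, 0.063) == pytest.approx(4.68, abs=0.005)

    def test_zero_bias(self):
        assert estimate_kappa(0.0, 0.063) == 0.0

    def test_switch_point(self):
        assert estimate_kappa(0.05, 0.05) == 1.0

    def test_zero_slope_rejected(self):
        with pytest.raises(DomainError):
            estimate_kappa(0.295, 0.0)


class TestHistograms:
    def test_parked_disk_occupancy(self):
        t = np.arange(100) / 30
        traj = Trajectory(t, np.full(100, 50.0), np.zeros(100))
        h = occupancy_distribution(traj, 10, DomainConfig(100.0))
        assert np.count_nonzero(h.density) == 1
        assert np.sum(h.density * h.bin_width) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_domain_frames_rejected(self):
        t = np.arange(3) / 30
        traj = Trajectory(t, np.array([10.0, 50.0, 120.0]), np.zeros(3))
        with pytest.raises(DataError):
            occupancy_distribution(traj, 10, DomainConfig(100.0))

    def test_occupancy_equals_empirical_binning(self):
        rng = np.random.default_rng(6)
        xs = rng.uniform(0, 100, 500)
        t = np.arange(500) / 30
        traj = Trajectory(t, xs, np.zeros(500))
        occ = occupancy_distribution(traj, 20, DomainConfig(100.0))
        direct = bin_positions(xs, 20, 100.0)
        assert np.array_equal(occ.density, direct.density)

    def test_direction_histogram_uniform_not_rejected(self):
        rng = np.random.default_rng(99)
        jumps = [make_jump(theta=t) for t in rng.uniform(-math.pi, math.pi, 10**4)]
        h = direction_histogram(jumps, 12)
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert h.pvalue > 0.01

    def test_direction_histogram_degenerate(self):
        jumps = [make_jump(theta=0.0) for _ in range(50)]
        h = direction_histogram(jumps, 8)
        assert h.probabilities.max() == pytest.approx(1.0)
        assert h.pvalue < 1e-6

    def test_empty_jumps_rejected(self):
        with pytest.raises(DataError):
            direction_histogram([], 8)


class TestRigidMotionInvariance:
    def test_translation_leaves_lengths(self):
        rng = np.random.default_rng(12)
        t = np.arange(50) / 30
        xs = np.cumsum(rng.uniform(0, 1, 50))
        ys = np.cumsum(rng.uniform(0, 1, 50))
        traj = Trajectory(t, xs, ys)
        runs = segment_runs(compute_speed(traj), SegmentationConfig(speed_threshold=5.0))
        j0 = extract_jumps(traj, runs)
        shifted = Trajectory(t, xs + 7.5, ys - 3.25)
        j1 = extract_jumps(shifted, runs)
        assert [a.length for a in j0] == pytest.approx([b.length for b in j1], rel=1e-12)

    def test_rotation_shifts_theta(self):
        phi = 0.7
        t = np.arange(20) / 30
        rng = np.random.default_rng(13)
        xs = np.cumsum(rng.uniform(0, 1, 20))
        ys = np.cumsum(rng.uniform(0, 1, 20))
        traj = Trajectory(t, xs, ys)
        rot = Trajectory(
            t, xs * math.cos(phi) - ys * math.sin(phi), xs * math.sin(phi) + ys * math.cos(phi)
        )
        runs = [(0, 19)]
        (j0,) = extract_jumps(traj, runs)
        (j1,) = extract_jumps(rot, runs)
        dtheta = (j1.theta - j0.theta + math.pi) % (2 * math.pi) - math.pi
        assert dtheta == pytest.approx(phi, abs=1e-12)
        assert j1.length == pytest.approx(j0.length, rel=1e-12)
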