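import numpy as np
import pytest
from dataclasses import replace

from reachfit import (
    TrialInvalidError,
    analyze_trial,
    decompose_rotation,
    detect_goal_arrival,
    fold_angle,
    minimum_jerk,
    peg_angle,
    simulate_trial,
)
from conftest import make_trajectory


def _marker_pair(theta_deg, half_span=10.0, n=None, z=40.0):
    """peg_a / peg_b trajectories realising an angle series (degrees)."""
    theta = np.atleast_1d(np.radians(theta_deg)).astype(float)
    if n is None:
        n = len(theta)
    arm = half_span * np.stack(
        [np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1
    )
    center = np.tile([0.0, 0.0, z], (n, 1))
    return (make_trajectory(center - arm, label="peg_a"),
            make_trajectory(center + arm, label="peg_b"))


class TestPegAngle:
    def test_axis_aligned_pairs(self):
        a, b = _marker_pair(np.zeros(6))
        assert np.allclose(peg_angle(a, b), 0.0, atol=1e-9)
        # markers along y: the raw orientation is 90 degrees
        a, b = _marker_pair(np.full(6, 90.0))
        delta = b.positions[0] - a.positions[0]
        assert np.degrees(np.arctan2(delta[1], delta[0])) == pytest.approx(90.0)

    def test_smooth_180_rotation_unwraps_without_jumps(self):
        tau = np.linspace(0, 1, 200)
        series = 180.0 * np.asarray(minimum_jerk(tau))
        a, b = _marker_pair(series)
        theta = peg_angle(a, b)
        assert theta[-1] == pytest.approx(180.0, abs=0.5)
        assert np.abs(np.diff(theta)).max() < 90.0

    def test_swapping_markers_leaves_relative_angle_unchanged(self):
        tau = np.linspace(0, 1, 120)
        series = -135.0 * np.asarray(minimum_jerk(tau))
        a, b = _marker_pair(series)
        assert np.allclose(peg_angle(a, b), peg_angle(b, a), atol=1e-9)

    def test_degenerate_pair_rejected(self):
        a, b = _marker_pair(np.zeros(6), half_span=0.3)
        with pytest.raises(TrialInvalidError):
            peg_angle(a, b)


class TestGoalArrival:
    def test_flyby_does_not_count(self):
        # the peg passes 15 mm from the goal, loops, then enters the radius
        t = np.linspace(0, 1, 100)
        x = np.where(t < 0.5, 100 * (0.5 - t), 15.0 * (1 - (t - 0.5) * 2))
        y = np.full_like(t, 15.0)
        y[t >= 0.5] = 15.0 - 14.0 * (t[t >= 0.5] - 0.5) * 2
        pos = np.stack([x, y, np.full_like(t, 40.0)], axis=1)
        traj = make_trajectory(pos, label="peg_center")
        f = detect_goal_arrival(traj, np.array([0.0, 0.0]), (0, 99), 10.0)
        d = np.linalg.norm(pos[:, :2], axis=1)
        assert d[f] < 10.0 and (d[:f] >= 10.0).all()

    def test_never_arriving_is_invalid(self):
        pos = np.tile([100.0, 0.0, 40.0], (50, 1))
        with pytest.raises(TrialInvalidError):
            detect_goal_arrival(make_trajectory(pos), np.zeros(2), (0, 49))

    def test_zero_radius_rejected(self):
        pos = np.zeros((50, 3))
        with pytest.raises(ValueError):
            detect_goal_arrival(make_trajectory(pos), np.zeros(2), (0, 49),
                                arrival_radius_mm=0.0)


class TestDecomposition:
    def _clean_profile(self, theta, rate=120.0):
        omega = np.gradient(theta) * rate
        return theta, omega

    def test_noise_free_two_pulse_recovery(self):
        # 90 deg during transport, 20 deg correction after arrival
        n = 360
        t = np.arange(n) / 120.0
        theta = 90.0 * np.asarray(minimum_jerk((t - 0.3) / 0.5))
        theta = theta + 20.0 * np.asarray(minimum_jerk((t - 1.8) / 0.3))
        theta, omega = self._clean_profile(theta)
        rp = decompose_rotation(theta, omega, arrival_frame=180,
                                transport_span=(0, n - 1), goal_angle=110.0,
                                rate_hz=120.0, settle_deg=0.0)
        true1 = np.sum(np.abs(omega[:180]) > 10.0) / 120.0 * 1000.0
        true2 = np.sum(np.abs(omega[180:]) > 10.0) / 120.0 * 1000.0
        assert rp.rota1_duration_ms == pytest.approx(true1, abs=1)
        assert rp.rota2_duration_ms == pytest.approx(true2, abs=1)
        assert rp.residual_angle_deg == pytest.approx(20.0, abs=0.5)

    def test_total_time_monotone_in_threshold(self):
        n = 360
        t = np.arange(n) / 120.0
        theta = 120.0 * np.asarray(minimum_jerk((t - 0.5) / 0.6))
        theta, omega = self._clean_profile(theta)
        totals = []
        for thr in (5.0, 10.0, 20.0, 40.0):
            rp = decompose_rotation(theta, omega, 180, (0, n - 1), 120.0,
                                    120.0, rotation_threshold_deg_s=thr,
                                    settle_deg=0.0)
            totals.append(rp.total_rotation_time_ms)
        assert totals == sorted(totals, reverse=True)

    def test_residual_folding(self):
        for d in (-730.0, -190.0, 10.0, 170.0, 350.0, 710.0):
            assert fold_angle(d + 360.0) == pytest.approx(fold_angle(d))
            assert 0.0 <= fold_angle(d) <= 180.0

    def test_arrival_outside_span_rejected(self):
        theta = np.zeros(100)
        with pytest.raises(ValueError):
            decompose_rotation(theta, theta, 90, (0, 50), 0.0, 120.0)


class TestStrategies:
    def test_adult_strategy_rotates_in_transport(self, profiles):
        r1 = r2 = res = 0.0
        n = 10
        for s in range(n):
            rec, _ = simulate_trial(profiles["adult"], "180", seed=60 + s)
            tm = analyze_trial(rec)
            r1 += tm.rota1_ms
            r2 += tm.rota2_ms
            res += tm.residual_angle_deg
        assert r2 / (r1 + r2) < 0.25
        assert res / n < 8.0

    def test_child_strategy_corrects_at_goal(self, profiles):
        r1 = r2 = res = 0.0
        n = 10
        for s in range(n):
            rec, _ = simulate_trial(profiles["child6"], "180", seed=60 + s)
            tm = analyze_trial(rec)
            r1 += tm.rota1_ms
            r2 += tm.rota2_ms
            res += tm.residual_angle_deg
        assert r2 > r1
        assert 20.0 <= res / n <= 25.0

    def test_round_peg_trial_reports_no_rotation_demand(self, profiles):
        prof = replace(profiles["adult"], noise_sd_mm=0.0, dropout_rate=0.0)
        rec, _ = simulate_trial(prof, "RP", seed=2)
        tm = analyze_trial(rec)
        assert tm.residual_angle_deg == 0.0
        assert tm.total_rotation_ms == pytest.approx(0.0, abs=50)

    def test_rotation_time_bounded_by_transport_duration(self, profiles):
        for group in ("adult", "child10", "child6"):
            for s in range(5):
                rec, _ = simulate_trial(profiles[group], "180", seed=80 + s)
                tm = analyze_trial(rec)
                assert tm.total_rotation_ms <= tm.transport_duration_ms + 1e-9
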