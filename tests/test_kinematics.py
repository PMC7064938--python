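import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reachfit import (
    VelocityProfile,
    detect_movement_units,
    minimum_jerk_vel,
    peak_time_difference,
    segment_metrics,
    tangential_velocity,
)
from conftest import make_trajectory, min_jerk_positions
from mu_oracle import oracle_movement_units


def bell_profile(peaks, n=240, rate=120.0, width=30):
    """Speed profile from separated minimum-jerk bells (peak amplitudes)."""
    v = np.zeros(n)
    for k, amp in enumerate(peaks):
        start = 10 + k * (width + 10)
        tau = (np.arange(n) - start) / width
        v += amp * np.asarray(minimum_jerk_vel(np.clip(tau, 0, 1))) / 1.875
    a = np.gradient(v) * rate
    return VelocityProfile(v=v, a=a, rate_hz=rate)


class TestTangentialVelocity:
    def test_uniform_motion(self):
        pos = np.outer(np.arange(100, dtype=float), [1.0, 0.0, 0.0])
        vp = tangential_velocity(make_trajectory(pos))
        assert np.allclose(vp.v, 120.0)
        assert np.allclose(vp.a[1:-1], 0.0, atol=1e-9)

    def test_stationary_marker(self):
        vp = tangential_velocity(make_trajectory(np.ones((50, 3))))
        assert np.allclose(vp.v, 0.0) and np.allclose(vp.a, 0.0)

    def test_min_jerk_peak_speed_matches_analytic_value(self):
        # a 260 mm reach in 846 ms peaks at 1.875 * A / D
        pos = min_jerk_positions(260.0, 0.846)
        vp = tangential_velocity(make_trajectory(pos))
        expected = 1.875 * 260.0 / 0.846
        assert vp.v.max() == pytest.approx(expected, rel=0.02)

    def test_translation_invariance(self, rng):
        pos = rng.normal(0, 10, (60, 3)).cumsum(axis=0)
        v1 = tangential_velocity(make_trajectory(pos)).v
        v2 = tangential_velocity(make_trajectory(pos + [500, -300, 80])).v
        assert np.allclose(v1, v2)

    def test_short_span_rejected(self):
        with pytest.raises(ValueError):
            tangential_velocity(make_trajectory(np.zeros((10, 3))), (3, 4))


class TestMovementUnits:
    def test_single_bell_is_one_unit(self):
        units = detect_movement_units(bell_profile([500.0]))
        assert len(units) == 1
        u = units[0]
        assert u.start_frame < u.peak_frame < u.end_frame
        assert u.rise >= 20 and u.fall >= 20

    def test_sub_threshold_second_bell_rejected(self):
        units = detect_movement_units(bell_profile([500.0, 15.0]))
        assert len(units) == 1

    def test_both_bells_above_threshold(self):
        units = detect_movement_units(bell_profile([500.0, 60.0]))
        assert len(units) == 2

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10**9))
    def test_matches_bruteforce_oracle_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 7)
        n = int(rng.integers(40, 300))
        v = np.zeros(n)
        for _ in range(k):
            start = rng.integers(0, max(1, n - 20))
            width = rng.integers(8, 60)
            amp = rng.uniform(3.0, 800.0)
            tau = (np.arange(n) - start) / width
            v += amp * np.asarray(minimum_jerk_vel(np.clip(tau, 0, 1)))
        v += np.abs(rng.normal(0, 1.0, n))
        a = np.gradient(v) * 120.0
        vp = VelocityProfile(v=v, a=a, rate_hz=120.0)
        got = [(u.start_frame, u.peak_frame, u.end_frame)
               for u in detect_movement_units(vp)]
        want = oracle_movement_units(v, a)
        assert got == want

    def test_well_separated_submovements_all_detected(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 6))
            amps = rng.uniform(45.0, 600.0, k)
            vp = bell_profile(list(amps), n=60 * k + 60, width=25)
            assert len(detect_movement_units(vp)) == k

    def test_lowering_threshold_never_reduces_count(self, rng):
        for _ in range(30):
            k = int(rng.integers(1, 6))
            amps = rng.uniform(5.0, 300.0, k)
            vp = bell_profile(list(amps), n=60 * k + 60, width=25)
            counts = [len(detect_movement_units(vp, min_delta_v=t))
                      for t in (40.0, 20.0, 10.0, 5.0)]
            assert counts == sorted(counts)

    def test_acceleration_clause_guards_slow_drifts(self):
        # a 60 mm/s bell spread over 20 s has peak acceleration ~ 9 mm/s^2;
        # raising the acceleration floor above that rejects the unit
        vp = bell_profile([60.0], n=3000, width=2400)
        assert len(detect_movement_units(vp, min_accel=5.0)) == 1
        assert len(detect_movement_units(vp, min_accel=50.0)) == 0


class TestSegmentMetrics:
    def test_symmetric_min_jerk_ppv_is_50(self):
        pos = min_jerk_positions(260.0, 0.8)
        traj = make_trajectory(pos)
        vp = tangential_velocity(traj)
        n_pad = 24
        span = (n_pad, len(pos) - n_pad - 1)
        m = segment_metrics(vp, traj, span)
        assert m.ppv_pct == pytest.approx(50.0, abs=1.0)
        assert m.n_mus == 1
        assert m.accel_phase_pct + m.decel_phase_pct == pytest.approx(100.0)

    def test_uniform_straight_line(self):
        pos = np.outer(np.linspace(0, 300, 301), [0.0, 1.0, 0.0])
        traj = make_trajectory(pos)
        vp = tangential_velocity(traj)
        m = segment_metrics(vp, traj, (0, 300))
        assert m.path_distance_mm == pytest.approx(300.0)
        assert m.avg_velocity_mm_s == pytest.approx(m.peak_velocity_mm_s)

    def test_peak_at_41_percent_splits_phases_41_59(self):
        n = 200
        v = np.concatenate([np.linspace(0, 500, 83),
                            np.linspace(500, 0, n - 83)[1:]])
        v = np.append(v, 0.0)
        traj = make_trajectory(np.zeros((len(v), 3)))
        vp = VelocityProfile(v=v, a=np.gradient(v) * 120, rate_hz=120.0)
        m = segment_metrics(vp, traj, (0, len(v) - 1))
        assert m.accel_phase_pct == pytest.approx(41.0, abs=0.5)
        assert m.decel_phase_pct == pytest.approx(59.0, abs=0.5)

    def test_path_distance_invariant_under_rotation(self, rng):
        pos = rng.normal(0, 20, (80, 3)).cumsum(axis=0)
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0],
                        [0, 0, 1.0]])
        t1 = make_trajectory(pos)
        t2 = make_trajectory(pos @ rot.T)
        span = (0, 79)
        m1 = segment_metrics(tangential_velocity(t1), t1, span)
        m2 = segment_metrics(tangential_velocity(t2), t2, span)
        assert m1.path_distance_mm == pytest.approx(m2.path_distance_mm)

    def test_all_zero_speed_is_an_error(self):
        traj = make_trajectory(np.zeros((50, 3)))
        vp = tangential_velocity(traj)
        with pytest.raises(ValueError):
            segment_metrics(vp, traj, (0, 49))


class TestPeakTimeDifference:
    def test_identical_profiles_give_zero(self):
        vp = bell_profile([400.0])
        assert peak_time_difference(vp, vp, (0, len(vp) - 1)) == 0.0

    def test_five_frame_lead_is_minus_41_7_ms(self):
        v = bell_profile([400.0]).v
        lead = np.roll(v, -5)
        mk = lambda x: VelocityProfile(v=x, a=np.gradient(x) * 120,
                                       rate_hz=120.0)
        d = peak_time_difference(mk(lead), mk(v), (0, len(v) - 1))
        assert d == pytest.approx(-41.67, abs=0.1)

    def test_simulated_index_lead_recovered_in_the_mean(self, profiles):
        from reachfit import analyze_trial, simulate_trial
        errs = []
        for s in range(30):
            rec, gt = simulate_trial(profiles["adult"], "180", seed=500 + s)
            tm = analyze_trial(rec)
            errs.append(tm.peak_time_diff_ms + gt.params["index_lead_ms"])
        assert abs(np.mean(errs)) < 9.0
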