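"""End-to-end per-trial analysis: raw recording -> flat metrics record."""

from __future__ import annotations

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .kinematics import (
    VelocityProfile,
    detect_movement_units,
    peak_time_difference,
    segment_metrics,
    tangential_velocity,
)
from .phases import PhaseBoundaries, segment_trial
from .rotation import angular_speed, decompose_rotation, detect_goal_arrival, peg_angle
from .stats import TrialMetrics
from .trial_io import (
    MarkerTrajectory,
    TrialInvalidError,
    TrialRecording,
    gap_fill,
    mirror_x,
    smooth,
)

_ANALYSIS_MARKERS = ("wrist", "index", "peg_a", "peg_b")


def preprocess(
    recording: TrialRecording, cfg: AnalysisConfig = DEFAULT_CONFIG
) -> tuple[TrialRecording, tuple[int, int]]:
    """Repair dropouts, smooth, and mirror left-hand trials.

    Returns the processed recording and the analysed frame span (inclusive)
    over which every hand/peg marker is valid.  Interior gaps beyond the
    manual limit, or edge gaps that push the span past the goal-visibility
    frame, invalidate the trial.
    """
    rec = mirror_x(recording) if recording.hand == "left" else recording.copy()
    n = rec.n_frames
    lo, hi = 0, n - 1
    for label in _ANALYSIS_MARKERS:
        traj = gap_fill(rec.markers[label], cfg.max_auto_gap,
                        cfg.max_manual_gap, cfg.allow_manual)
        if traj.exclude_reason:
            raise TrialInvalidError(
                f"{label}: {traj.exclude_reason}"
            )
        valid = traj.valid
        first = int(np.argmax(valid))
        last = n - 1 - int(np.argmax(valid[::-1]))
        if not valid[first : last + 1].all():
            raise TrialInvalidError(f"{label}: unfilled interior gap")
        lo, hi = max(lo, first), min(hi, last)
        rec.markers[label] = traj
    if lo > rec.goal_visible_frame:
        raise TrialInvalidError("marker data start after goal visibility")
    for label in _ANALYSIS_MARKERS:
        rec.markers[label] = smooth(rec.markers[label], cfg.cutoff_hz,
                                    cfg.filter_order, span=(lo, hi + 1))
    g = gap_fill(rec.markers["goal"], cfg.max_auto_gap, cfg.max_manual_gap,
                 cfg.allow_manual, span=(rec.goal_visible_frame, n))
    rec.markers["goal"] = g
    return rec, (lo, hi)


def peg_center_trajectory(rec: TrialRecording) -> MarkerTrajectory:
    """Midpoint of the two peg-top markers."""
    a, b = rec.markers["peg_a"], rec.markers["peg_b"]
    return MarkerTrajectory(
        label="peg_center",
        positions=0.5 * (a.positions + b.positions),
        valid=a.valid & b.valid,
        rate_hz=a.rate_hz,
    )


def _full_velocity(traj: MarkerTrajectory, span: tuple[int, int]) -> VelocityProfile:
    """Velocity profile indexed in recording frames (zero outside span)."""
    vp = tangential_velocity(traj, span)
    n = traj.n_frames
    v = np.zeros(n)
    a = np.zeros(n)
    lo, hi = span
    v[lo : hi + 1] = vp.v
    a[lo : hi + 1] = vp.a
    return VelocityProfile(v=v, a=a, rate_hz=traj.rate_hz,
                           source_marker=traj.label)


def goal_position(rec: TrialRecording) -> np.ndarray:
    """Mean goal-marker position over its valid frames."""
    g = rec.markers["goal"]
    if not g.valid.any():
        raise TrialInvalidError("goal marker never visible")
    return g.positions[g.valid].mean(axis=0)


def analyze_trial(
    recording: TrialRecording,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
    return_details: bool = False,
):
    """Run the full kinematic analysis of one trial.

    Returns a :class:`~reachfit.stats.TrialMetrics` record (and, when
    ``return_details`` is set, the phase boundaries and rotation profile).
    """
    rec, (lo, hi) = preprocess(recording, cfg)
    wrist = rec.markers["wrist"]
    index = rec.markers["index"]
    peg = peg_center_trajectory(rec)
    vp_wrist = _full_velocity(wrist, (lo, hi))
    vp_index = _full_velocity(index, (lo, hi))
    vp_peg = _full_velocity(peg, (lo, hi))
    goal_xy = goal_position(rec)[:2]

    bounds = segment_trial(vp_wrist, vp_peg, wrist, peg, goal_xy,
                           rec.goal_visible_frame, cfg)
    reach_span = (bounds.reach_start_frame, bounds.reach_end_frame)
    transport_span = (bounds.transport_start_frame, bounds.transport_end_frame)
    mu_kw = dict(min_delta_v=cfg.mu_min_delta_v_mm_s,
                 min_accel=cfg.mu_min_accel_mm_s2)

    rw = segment_metrics(vp_wrist, wrist, reach_span, **mu_kw)
    ri = segment_metrics(vp_index, index, reach_span, **mu_kw)
    tw = segment_metrics(vp_wrist, wrist, transport_span, **mu_kw)
    ti = segment_metrics(vp_index, index, transport_span, **mu_kw)
    tp = segment_metrics(vp_peg, peg, transport_span, **mu_kw)
    pdiff = peak_time_difference(vp_index, vp_wrist, reach_span)

    # rotation decomposition
    theta = peg_angle(rec.markers["peg_a"], rec.markers["peg_b"], (lo, hi))
    omega = angular_speed(theta, rec.rate_hz, cfg.omega_smooth_hz)
    arrival = detect_goal_arrival(peg, goal_xy, transport_span,
                                  cfg.arrival_radius_mm)
    goal_angle = rec.condition_angle
    if goal_angle is not None and recording.hand == "left":
        goal_angle = -goal_angle  # mirrored geometry flips rotation sense
    rot = decompose_rotation(theta, omega, arrival, transport_span,
                             goal_angle, rec.rate_hz,
                             cfg.rotation_threshold_deg_s, theta_offset=lo,
                             trigger_factor=cfg.rotation_trigger_factor,
                             min_run_frames=cfg.rotation_min_frames,
                             settle_deg=cfg.rotation_settle_deg)

    # share of transport movement units in the fitting stage (after arrival)
    sub = VelocityProfile(
        v=vp_wrist.v[transport_span[0] : transport_span[1] + 1],
        a=vp_wrist.a[transport_span[0] : transport_span[1] + 1],
        rate_hz=rec.rate_hz,
    )
    units = detect_movement_units(sub, **mu_kw)
    if units:
        n_fit = sum(1 for u in units
                    if u.peak_frame + transport_span[0] >= arrival)
        fit_frac = n_fit / len(units)
    else:
        fit_frac = float("nan")

    gap = float(np.linalg.norm(
        index.positions[transport_span[0] : transport_span[1] + 1]
        - wrist.positions[transport_span[0] : transport_span[1] + 1],
        axis=1,
    ).mean())

    tm = TrialMetrics(
        trial_id=rec.trial_id,
        group=rec.group_label,
        condition=rec.condition,
        hand=recording.hand,
        latency_ms=bounds.latency_ms,
        reach_duration_ms=rw.duration_ms,
        reach_wrist_mus=rw.n_mus,
        reach_index_mus=ri.n_mus,
        reach_wrist_peak_v=rw.peak_velocity_mm_s,
        reach_wrist_peak_time_ms=rw.time_of_peak_ms,
        reach_wrist_ppv_pct=rw.ppv_pct,
        reach_wrist_decel_pct=rw.decel_phase_pct,
        reach_wrist_avg_v=rw.avg_velocity_mm_s,
        reach_wrist_dist_mm=rw.path_distance_mm,
        reach_index_peak_v=ri.peak_velocity_mm_s,
        reach_index_peak_time_ms=ri.time_of_peak_ms,
        reach_index_avg_v=ri.avg_velocity_mm_s,
        reach_index_dist_mm=ri.path_distance_mm,
        peak_time_diff_ms=pdiff,
        grasp_duration_ms=bounds.grasp_duration_ms,
        transport_duration_ms=tw.duration_ms,
        transport_wrist_mus=tw.n_mus,
        transport_index_mus=ti.n_mus,
        transport_peg_mus=tp.n_mus,
        transport_wrist_avg_v=tw.avg_velocity_mm_s,
        transport_index_avg_v=ti.avg_velocity_mm_s,
        transport_wrist_dist_mm=tw.path_distance_mm,
        transport_index_dist_mm=ti.path_distance_mm,
        fitting_mu_fraction=fit_frac,
        rota1_ms=rot.rota1_duration_ms,
        rota2_ms=rot.rota2_duration_ms,
        total_rotation_ms=rot.total_rotation_time_ms,
        residual_angle_deg=rot.residual_angle_deg,
        arrival_frame=arrival,
        wrist_index_gap_mm=gap,
        flags=";".join(bounds.flags),
    )
    if return_details:
        return tm, bounds, rot
    return tm


def analyze_trials(
    trials, cfg: AnalysisConfig = DEFAULT_CONFIG
):
    """Analyse an iterable of recordings; returns (metrics list, failures).

    Failures are (trial_id, reason) pairs for trials the criteria could not
    segment (the acquisition-time analogue is repeating the trial).
    """
    out, failures = [], []
    for rec in trials:
        try:
            out.append(analyze_trial(rec, cfg))
        except TrialInvalidError as exc:
            failures.append((rec.trial_id, str(exc)))
    return out, failures
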