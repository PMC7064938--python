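"""Synthetic reach-grasp-transport-fit trials with known ground truth.

Trials are assembled from superposed minimum-jerk submovements — the
standard model for bell-shaped speed profiles in goal-directed reaching —
on the task geometry of the peg-fitting protocol: a peg grasped from a
start holder and carried 250 mm to a goal holder whose slot orientation
(0, 90, 180 or -90 degrees, or a round-peg baseline) dictates how much the
peg must be rotated.  Three calibrated actor profiles emulate the
statistical structure of an adult, a 10-year-old and a 6-year-old group:
movement-onset latency, approach duration and segmentation, grasp dwell,
transport duration and corrective submovement counts, and — centrally —
the rotation strategy: rotating the peg predictively while transporting it
(in_transport) versus correcting the orientation after arriving at the
goal (at_goal).

Every generated trial carries a :class:`GroundTruth` record whose event
frames (onset, contact, lift, arrival, seating, hand return) and rotation
components are computed from the noise-free trajectories by construction,
so each pipeline stage can be validated without any human data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .trial_io import (
    CONDITIONS,
    MARKER_LABELS,
    MarkerTrajectory,
    TrialRecording,
    write_trial,
)

# scene geometry (mm): x frontoparallel, y depth, z vertical; right hand
START_HOLDER = np.array([125.0, 300.0, 0.0])
GOAL_HOLDER = np.array([-125.0, 300.0, 0.0])   # 250 mm holder separation
PEG_MARKER_HEIGHT = 40.0                        # peg-top markers above table
PEG_MARKER_HALF_SPAN = 10.0                     # 20 mm between the two markers
GRASP_OFFSET = np.array([0.0, -15.0, 25.0])     # hand relative to holder centre
LIFT_HEIGHT = 30.0
RATE_HZ = 120.0

# per-condition demand on orientation planning (0 = none, 1 = hardest)
DIFFICULTY = {"RP": 0.0, "0": 0.15, "-90": 0.5, "90": 0.65, "180": 1.0}
GOAL_ANGLE = {"RP": 0.0, "0": 0.0, "90": 90.0, "180": 180.0, "-90": -90.0}


def minimum_jerk(tau: np.ndarray | float) -> np.ndarray | float:
    """Normalised minimum-jerk position profile, clipped to [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_vel(tau: np.ndarray | float) -> np.ndarray | float:
    """Derivative of the normalised profile (peak 1.875 at tau = 0.5)."""
    tau = np.asarray(tau, dtype=float)
    out = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    return np.where((tau < 0) | (tau > 1), 0.0, out)


@dataclass
class Submovement:
    """One minimum-jerk displacement leg (3D vector or scalar angle)."""

    t0: float
    duration: float
    vector: np.ndarray  # shape (3,) for translation, (1,) for angle


def _displacement(subs: list[Submovement], t: np.ndarray, dim: int) -> np.ndarray:
    out = np.zeros((len(t), dim))
    for sm in subs:
        s = minimum_jerk((t - sm.t0) / sm.duration)
        out += np.outer(s, sm.vector)
    return out


def _velocity(subs: list[Submovement], t: np.ndarray, dim: int) -> np.ndarray:
    out = np.zeros((len(t), dim))
    for sm in subs:
        s = minimum_jerk_vel((t - sm.t0) / sm.duration) / sm.duration
        out += np.outer(s, sm.vector)
    return out


# ---------------------------------------------------------------------------
# Actor profiles
# ---------------------------------------------------------------------------

@dataclass
class GroupProfile:
    """Generator parameters for one actor group; (mean, sd) pairs in ms/mm.

    Orientation parameters (``residual_angle_deg``, ``rota1_ms``,
    ``rota2_ms``) refer to the 180-degree condition and are scaled down for
    easier conditions.  Defaults are calibration values seeded from typical
    adult / 10-year / 6-year performance on this task; they define the
    emulated study conditions, not a reproduction of any human dataset.
    """

    name: str
    latency_ms: tuple[float, float]
    reach_amplitude_mm: tuple[float, float]
    wrist_peak_v_mm_s: tuple[float, float]
    reach_duration_ms: tuple[float, float]
    reach_mus: float                       # mean wrist MU count in the reach
    index_extra_mus: float                 # extra index-finger MUs (mean)
    grasp_dwell_ms: tuple[float, float]
    transport_translate_ms: tuple[float, float]
    transport_mus: tuple[float, float]     # wrist MU count over transport-to-fit
    rotation_strategy: str                 # in_transport | at_goal | mixed
    at_goal_weight: float                  # P(trial uses the at_goal strategy)
    residual_angle_deg: tuple[float, float]
    rota1_ms: tuple[float, float]
    rota2_ms: tuple[float, float]
    index_lead_ms: tuple[float, float]
    wrist_index_gap_mm: tuple[float, float]
    coupling: float = 0.3                  # reach/transport latent correlation
    noise_sd_mm: float = 0.3
    dropout_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.rotation_strategy not in ("in_transport", "at_goal", "mixed"):
            raise ValueError("unknown rotation strategy")
        if not 0.0 <= self.at_goal_weight <= 1.0:
            raise ValueError("at_goal_weight must lie in [0, 1]")
        for nm in ("latency_ms", "reach_duration_ms", "grasp_dwell_ms",
                   "transport_translate_ms"):
            if getattr(self, nm)[0] <= 0:
                raise ValueError(f"{nm} mean must be positive")
        # peak speed must allow covering the amplitude within the budget
        d_main = 1.875 * self.reach_amplitude_mm[0] / self.wrist_peak_v_mm_s[0]
        if d_main * 1000.0 > self.reach_duration_ms[0] * 1.15:
            raise ValueError("infeasible profile: peak velocity too low for "
                             "the reach amplitude and duration")


def default_profiles() -> dict[str, GroupProfile]:
    """The three calibrated actor groups."""
    return {
        "adult": GroupProfile(
            name="adult",
            latency_ms=(296.0, 60.0),
            reach_amplitude_mm=(260.0, 12.0),
            wrist_peak_v_mm_s=(654.0, 50.0),
            reach_duration_ms=(846.0, 70.0),
            reach_mus=1.3,
            index_extra_mus=1.8,
            grasp_dwell_ms=(77.0, 25.0),
            transport_translate_ms=(650.0, 55.0),
            transport_mus=(6.5, 1.6),
            rotation_strategy="in_transport",
            at_goal_weight=0.0,
            residual_angle_deg=(5.6, 1.5),
            rota1_ms=(520.0, 70.0),
            rota2_ms=(140.0, 35.0),
            index_lead_ms=(27.0, 8.0),
            wrist_index_gap_mm=(101.0, 8.0),
            coupling=0.40,
        ),
        "child10": GroupProfile(
            name="child10",
            latency_ms=(128.0, 45.0),
            reach_amplitude_mm=(305.0, 14.0),
            wrist_peak_v_mm_s=(942.0, 70.0),
            reach_duration_ms=(733.0, 65.0),
            reach_mus=1.7,
            index_extra_mus=1.6,
            grasp_dwell_ms=(64.0, 22.0),
            transport_translate_ms=(600.0, 55.0),
            transport_mus=(7.5, 1.8),
            rotation_strategy="mixed",
            at_goal_weight=0.5,
            residual_angle_deg=(17.3, 3.5),
            rota1_ms=(450.0, 70.0),
            rota2_ms=(620.0, 90.0),
            index_lead_ms=(51.0, 10.0),
            wrist_index_gap_mm=(98.0, 8.0),
            coupling=0.25,
        ),
        "child6": GroupProfile(
            name="child6",
            latency_ms=(187.0, 55.0),
            reach_amplitude_mm=(307.0, 14.0),
            wrist_peak_v_mm_s=(852.0, 65.0),
            reach_duration_ms=(905.0, 85.0),
            reach_mus=2.4,
            index_extra_mus=1.0,
            grasp_dwell_ms=(254.0, 55.0),
            transport_translate_ms=(650.0, 60.0),
            transport_mus=(13.3, 2.2),
            rotation_strategy="at_goal",
            at_goal_weight=1.0,
            residual_angle_deg=(22.5, 1.8),
            rota1_ms=(550.0, 80.0),
            rota2_ms=(940.0, 110.0),
            index_lead_ms=(55.0, 10.0),
            wrist_index_gap_mm=(68.0, 6.0),
            coupling=0.60,
        ),
    }


@dataclass
class GroundTruth:
    """Event frames, counts and rotation components implied by construction."""

    params: dict
    onset_frame: int
    contact_frame: int
    lift_start_frame: int
    lift_cross_frame: int       # peg 1 mm above resting height
    arrival_frame: int
    seat_frame: int
    return_cross_frame: int     # wrist at 60 mm/s moving away
    n_frames: int
    reach_wrist_mus: int
    reach_index_mus: int
    transport_wrist_mus: int
    fitting_wrist_mus: int      # transport MUs occurring after arrival
    rota1_ms: float
    rota2_ms: float
    residual_angle_deg: float
    goal_angle_deg: float | None

    @property
    def latency_ms(self) -> float:
        return self.params["latency_ms"]

    @property
    def grasp_dwell_ms(self) -> float:
        return self.params["grasp_dwell_ms"]


def _draw(rng: np.random.Generator, mean_sd: tuple[float, float],
          lo: float | None = None, shift: float = 0.0) -> float:
    x = rng.normal(mean_sd[0], mean_sd[1]) + shift
    if lo is not None:
        x = max(lo, x)
    return x


def _first_crossing(t: np.ndarray, series: np.ndarray, level: float,
                    after: float = -np.inf) -> float:
    mask = (t >= after) & (series >= level)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise RuntimeError("constructed trial never crosses expected level")
    return float(t[idx[0]])


def simulate_trial(
    profile: GroupProfile,
    condition: str,
    seed: int | np.random.Generator | None = None,
    hand_used: str = "right",
    trial_id: str = "",
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one labelled trial for a profile and goal condition.

    Left-hand trials are produced by mirroring the right-hand geometry
    about the mid-sagittal plane (the physical rotation direction flips
    with it).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rate = RATE_HZ
    diff = DIFFICULTY[condition]
    demand = 0.35 + 0.65 * diff
    if hand_used not in ("left", "right"):
        raise ValueError("hand_used must be 'left' or 'right'")
    # normalised so that a flat average over the five conditions is 1:
    # group-level parameter means then hold across a full cohort
    demand_rel = demand / 0.649
    goal_signed = GOAL_ANGLE[condition]
    if hand_used == "left":
        # build the mirrored actor's world: the slot orientation flips
        # sign under reflection; positions are mirrored after assembly
        goal_signed = -goal_signed

    # ---- parameter draws -------------------------------------------------
    # latent per-trial "sluggishness": a slow, deliberate trial has a lower
    # peak speed, a longer grasp and transport, and more corrections, which
    # couples reach-phase and transport-phase kinematics across trials
    u = rng.standard_normal()
    c = profile.coupling
    root = math.sqrt(1 - c * c)

    def mix(sign=1.0):
        return sign * c * u + root * rng.standard_normal()

    e_reach = mix()
    e_trans = mix()

    latency = _draw(rng, profile.latency_ms, lo=8.0) / 1000.0
    amplitude = _draw(rng, profile.reach_amplitude_mm, lo=150.0)
    m, sd = profile.wrist_peak_v_mm_s
    peak_v = max(300.0, m + sd * mix(-1.0))
    m, sd = profile.grasp_dwell_ms
    dwell = max(30.0, m + sd * mix()) / 1000.0
    m, sd = profile.transport_translate_ms
    d_translate = max(0.35, (m + sd * mix()) / 1000.0)
    lead = _draw(rng, profile.index_lead_ms, lo=0.0) / 1000.0
    gap = _draw(rng, profile.wrist_index_gap_mm, lo=30.0)

    # corrective counts share the latent factor: deliberate trials are
    # also more segmented
    n_reach_extra = min(3, int(rng.poisson(
        max(0.0, profile.reach_mus - 1.0) * math.exp(1.0 * c * u)
    )))
    mus_mean, mus_sd = profile.transport_mus
    target_mus = 3 + (mus_mean - 3 + mus_sd * e_trans) * demand_rel
    n_pairs = max(0, int(round((target_mus - 3) / 2.0)))
    if goal_signed != 0.0 and n_pairs == 0:
        n_pairs = 1                       # at least one at-goal adjustment
    leg_dur_scale = max(0.6, 1.0 + 0.3 * c * u)

    use_at_goal = rng.random() < profile.at_goal_weight
    if condition == "RP":
        residual = 0.0
    else:
        residual = max(0.0, rng.normal(profile.residual_angle_deg[0] * demand,
                                       profile.residual_angle_deg[1]))
    if goal_signed != 0.0:
        residual_signed = residual * (1.0 if goal_signed > 0 else -1.0)
        theta_transport = goal_signed - residual_signed
    else:
        # 0-degree slot: a misjudged arrival orientation, corrected at goal
        residual_signed = residual * float(rng.choice([-1.0, 1.0]))
        theta_transport = -residual_signed

    # ---- scene -----------------------------------------------------------
    grasp_pos = START_HOLDER + GRASP_OFFSET
    goal_grasp_pos = GOAL_HOLDER + GRASP_OFFSET
    peg_rest = START_HOLDER + np.array([0.0, 0.0, PEG_MARKER_HEIGHT])
    approach_dir = np.array([0.35, -0.93, -0.05])
    approach_dir /= np.linalg.norm(approach_dir)
    rest_pos = grasp_pos + amplitude * approach_dir

    goal_visible_t = 0.2
    hand_subs: list[Submovement] = []
    index_only: list[Submovement] = []
    peg_only: list[Submovement] = []
    angle_subs: list[Submovement] = []

    # ---- reach -----------------------------------------------------------
    # the main submovement lands short of the grasp point; corrective
    # submovements cover the remaining undershoot
    undershoot = rng.uniform(10.0, 25.0) if n_reach_extra else 0.0
    main_vec = (grasp_pos + undershoot * approach_dir) - rest_pos
    a_main = float(np.linalg.norm(main_vec))
    d_main = 1.875 * a_main / peak_v
    # place the main submovement so wrist speed crosses 20 mm/s exactly at
    # goal_visible + latency
    tau_star = brentq(lambda x: (a_main / d_main) * 30 *
                      (x**2 - 2 * x**3 + x**4) - 20.0, 1e-6, 0.5)
    t0_reach = goal_visible_t + latency - tau_star * d_main
    hand_subs.append(Submovement(t0_reach, d_main, main_vec))
    t = t0_reach + d_main
    if n_reach_extra:
        budget = max(0.10, (profile.reach_duration_ms[0] / 1000.0 - d_main)
                     * (1.0 + 0.6 * e_reach))
        d_each = min(0.25, max(0.10, budget / n_reach_extra))
        remaining = undershoot * approach_dir
        for k in range(n_reach_extra):
            frac = 1.0 / (n_reach_extra - k)
            step = remaining * frac if k < n_reach_extra - 1 else remaining
            jitter = rng.normal(0.0, 2.0, 3) if k < n_reach_extra - 1 else 0.0
            vec = -step + jitter
            hand_subs.append(Submovement(t, d_each, vec))
            remaining = remaining - step + (jitter if np.ndim(jitter) else 0.0)
            t += d_each + rng.integers(0, 2) / rate
    t_contact = t

    # index-finger opening perturbations during the approach
    n_idx_pairs = min(2, int(rng.poisson(profile.index_extra_mus / 2.0)))
    for _ in range(n_idx_pairs):
        t0 = t0_reach + rng.uniform(0.2, 0.7) * d_main
        amp = rng.uniform(8.0, 15.0)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        d_p = rng.uniform(0.08, 0.12)
        index_only.append(Submovement(t0, d_p, amp * direction))
        index_only.append(Submovement(t0 + d_p, d_p, -amp * direction))

    # peg jostle at contact (horizontal only): the object-motion signature
    # of touch that terminates the approach
    j_dir = rng.standard_normal(2)
    j_dir = np.array([j_dir[0], j_dir[1], 0.0]) / np.linalg.norm(j_dir)
    peg_only.append(Submovement(t_contact, 0.05, 2.5 * j_dir))
    peg_only.append(Submovement(t_contact + 0.05, 0.05, -2.5 * j_dir))

    # ---- grasp dwell then transport -------------------------------------
    # the lift leg starts slightly early so the 1 mm height crossing (the
    # defined end of the grasp phase) falls exactly at contact + dwell
    d_lift = 0.08
    tau_1mm = (1.0 / (10.0 * LIFT_HEIGHT)) ** (1.0 / 3.0)  # s(tau) ~ 10 tau^3
    t_lift = t_contact + dwell - tau_1mm * d_lift
    hand_subs.append(Submovement(t_lift, d_lift, np.array([0.0, 0.0, LIFT_HEIGHT])))
    t_tr = t_lift + d_lift - 0.02
    hand_subs.append(Submovement(t_tr, d_translate, goal_grasp_pos - grasp_pos))
    t_hover = t_tr + d_translate

    # transport rotation (Rota I window): orienting the peg starts as it
    # is picked up and is finished well before the goal radius is entered
    if theta_transport != 0.0:
        d_rot1 = (_draw(rng, profile.rota1_ms, lo=200.0) / 1000.0
                  * (0.3 + 0.7 * abs(theta_transport) / 180.0))
        t_rot1 = t_lift + 0.02
        d_rot1 = min(d_rot1, t_tr + 0.78 * d_translate - t_rot1)
        angle_subs.append(Submovement(t_rot1, d_rot1,
                                      np.array([theta_transport])))

    # ---- fitting corrections at the goal ---------------------------------
    # the first correction overlaps the translate deceleration so the peg
    # centre never comes to a sustained rest before the peg is seated
    t_fit = t_hover - 0.05
    base_leg = 0.155 if profile.reach_mus < 2.0 else 0.135
    for _ in range(n_pairs):
        amp = rng.uniform(8.0, 18.0)
        direction = rng.standard_normal(2)
        direction = np.array([direction[0], direction[1], 0.0])
        direction /= np.linalg.norm(direction)
        for sign in (1.0, -1.0):
            d_leg = max(0.09, rng.normal(base_leg, 0.015)) * leg_dur_scale
            hand_subs.append(Submovement(t_fit, d_leg, sign * amp * direction))
            t_fit += 0.85 * d_leg          # 15 % overlap between legs
    # index-finger micro-adjustments while fitting
    for _ in range(min(1, int(rng.poisson(0.6)))):
        t0 = t_hover + rng.uniform(0.0, max(0.05, t_fit - t_hover - 0.2))
        amp = rng.uniform(8.0, 12.0)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        d_p = 0.09
        index_only.append(Submovement(t0, d_p, amp * direction))
        index_only.append(Submovement(t0 + d_p, d_p, -amp * direction))

    # corrective rotation at the goal (Rota II window)
    if condition != "RP":
        if use_at_goal and residual > 0.5:
            d_rot2 = _draw(rng, profile.rota2_ms, lo=250.0) / 1000.0 * demand
            # discrete correction steps, each large enough to be a clear
            # rotation episode (roughly 8 degrees or more per step)
            n_steps = max(1, min(3, int(residual // 8.0)))
            t0 = t_hover + 3.0 / rate
            for k in range(n_steps):
                frac = residual_signed / n_steps
                d_step = d_rot2 / n_steps
                angle_subs.append(Submovement(t0, d_step, np.array([frac])))
                t0 += d_step * 1.02
            t_fit = max(t_fit, t0 + 0.02)
        elif residual > 0.5:
            d_rot2 = max(0.08, _draw(rng, profile.rota2_ms, lo=60.0) / 1000.0
                         * (0.3 + 0.7 * demand))
            angle_subs.append(Submovement(t_hover + 3.0 / rate, d_rot2,
                                          np.array([residual_signed])))
            t_fit = max(t_fit, t_hover + 3.0 / rate + d_rot2 + 0.02)
        elif profile.at_goal_weight > 0.5:
            # orientation wobble without net demand (RP handled below)
            wob = rng.uniform(4.0, 8.0)
            t0 = t_hover + 3.0 / rate
            angle_subs.append(Submovement(t0, 0.12, np.array([wob])))
            angle_subs.append(Submovement(t0 + 0.125, 0.12, np.array([-wob])))
            t_fit = max(t_fit, t0 + 0.27)
    elif profile.at_goal_weight > 0.5:
        wob = rng.uniform(3.0, 6.0)
        t0 = t_hover + 3.0 / rate
        angle_subs.append(Submovement(t0, 0.12, np.array([wob])))
        angle_subs.append(Submovement(t0 + 0.125, 0.12, np.array([-wob])))
        t_fit = max(t_fit, t0 + 0.27)

    # ---- descent, detach, return ----------------------------------------
    t_descent = t_fit + 1.0 / rate
    d_descent = 0.15
    hand_subs.append(Submovement(t_descent, d_descent,
                                 np.array([0.0, 0.0, -LIFT_HEIGHT])))
    t_seat = t_descent + d_descent
    t_return = t_seat + 0.15
    d_return = 0.5
    return_vec = 0.8 * (rest_pos - goal_grasp_pos)
    hand_subs.append(Submovement(t_return, d_return, return_vec))
    t_end = t_return + d_return + 0.15
    n_frames = int(math.ceil(t_end * rate))
    frames_t = np.arange(n_frames) / rate

    # ---- assemble noise-free marker series --------------------------------
    wrist_arr = (np.asarray(rest_pos)[None, :]
                 + _displacement(hand_subs, frames_t, 3))
    hand_shift = np.asarray(rest_pos)[None, :] + _displacement(
        hand_subs, frames_t + lead, 3
    )
    off_dir = np.array([-0.25, 0.55, 0.35])
    off_dir /= np.linalg.norm(off_dir)
    index_arr = (hand_shift + gap * off_dir
                 + _displacement(index_only, frames_t, 3))

    hand_at_contact = np.asarray(rest_pos) + _displacement(
        hand_subs, np.array([t_contact]), 3
    )[0]
    attached = (frames_t >= t_contact) & (frames_t < t_seat)
    peg_center = np.tile(peg_rest, (n_frames, 1))
    peg_center[attached] = peg_rest + (wrist_arr[attached] - hand_at_contact)
    seated_pos = peg_rest + (goal_grasp_pos - grasp_pos)
    peg_center[frames_t >= t_seat] = seated_pos
    peg_center += _displacement(peg_only, frames_t, 3)

    theta0 = 0.0
    theta = theta0 + _displacement(angle_subs, frames_t, 1)[:, 0]
    rad = np.radians(theta)
    arm = PEG_MARKER_HALF_SPAN * np.stack(
        [np.cos(rad), np.sin(rad), np.zeros_like(rad)], axis=1
    )
    peg_a = peg_center - arm
    peg_b = peg_center + arm
    goal_marker = np.tile(GOAL_HOLDER + np.array([0.0, 0.0, 2.0]),
                          (n_frames, 1))

    # ---- ground-truth events from the noise-free construction ------------
    dense = np.arange(0.0, t_end, 1.0 / (8 * rate))
    v_hand = np.linalg.norm(_velocity(hand_subs, dense, 3), axis=1)
    t_onset = _first_crossing(dense, v_hand, 20.0, after=goal_visible_t)
    z_peg = peg_rest[2] + _displacement(
        [s for s in hand_subs if s.t0 >= t_lift - 1e-9], dense, 3
    )[:, 2]
    t_lift_cross = _first_crossing(dense, z_peg - peg_rest[2], 1.0,
                                   after=t_lift)
    # peg centre on the dense grid (attached until seated)
    hand_dense = np.asarray(rest_pos)[None, :] + _displacement(
        hand_subs, dense, 3
    )
    peg_dense = np.tile(peg_rest, (len(dense), 1))
    att = (dense >= t_contact) & (dense < t_seat)
    peg_dense[att] = peg_rest + (hand_dense[att] - hand_at_contact)
    peg_dense[dense >= t_seat] = seated_pos
    d_goal = np.linalg.norm(peg_dense[:, :2] - GOAL_HOLDER[None, :2], axis=1)
    t_arrival = _first_crossing(dense, (d_goal < 10.0).astype(float), 0.5,
                                after=t_tr)
    # hand returning: radial component of horizontal velocity away from the
    # goal at half the return threshold, with speed at the threshold
    radial = hand_dense[:, :2] - GOAL_HOLDER[None, :2]
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    v_xy = _velocity(hand_subs, dense, 3)[:, :2]
    away = (radial * v_xy).sum(axis=1) >= 30.0
    t_ret_cross = _first_crossing(
        dense, np.where(away, v_hand, 0.0), 60.0, after=t_seat
    )
    omega_dense = _velocity(angle_subs, dense, 1)[:, 0]
    dt = dense[1] - dense[0]
    rotating = np.abs(omega_dense) > 10.0
    win = (dense >= t_lift) & (dense <= t_ret_cross)
    rota1_true = float(rotating[win & (dense < t_arrival)].sum() * dt * 1000.0)
    rota2_true = float(rotating[win & (dense >= t_arrival)].sum() * dt * 1000.0)
    theta_arr = float(
        theta0 + _displacement(angle_subs, np.array([t_arrival]), 1)[0, 0]
    )
    if condition == "RP":
        residual_true = 0.0
    else:
        residual_true = abs((theta_arr - goal_signed + 180.0) % 360.0 - 180.0)

    goal_visible_frame = int(round(goal_visible_t * rate))
    gt = GroundTruth(
        params={
            "latency_ms": latency * 1000.0,
            "grasp_dwell_ms": dwell * 1000.0,
            "reach_amplitude_mm": amplitude,
            "wrist_peak_v_mm_s": 1.875 * a_main / d_main,
            "translate_ms": d_translate * 1000.0,
            "index_lead_ms": lead * 1000.0,
            "wrist_index_gap_mm": gap,
            "strategy": "at_goal" if use_at_goal else "in_transport",
        },
        onset_frame=int(round(t_onset * rate)),
        contact_frame=int(round(t_contact * rate)),
        lift_start_frame=int(round(t_lift * rate)),
        lift_cross_frame=int(round(t_lift_cross * rate)),
        arrival_frame=int(round(t_arrival * rate)),
        seat_frame=int(round(t_seat * rate)),
        return_cross_frame=int(round(t_ret_cross * rate)),
        n_frames=n_frames,
        reach_wrist_mus=1 + n_reach_extra,
        reach_index_mus=1 + n_reach_extra + 2 * n_idx_pairs,
        transport_wrist_mus=3 + 2 * n_pairs,
        fitting_wrist_mus=1 + 2 * n_pairs,
        rota1_ms=rota1_true,
        rota2_ms=rota2_true,
        residual_angle_deg=residual_true,
        goal_angle_deg=None if condition == "RP" else goal_signed,
    )

    # ---- noise, dropouts, packaging --------------------------------------
    series = {
        "wrist": wrist_arr, "index": index_arr, "peg_a": peg_a,
        "peg_b": peg_b, "goal": goal_marker,
    }
    markers: dict[str, MarkerTrajectory] = {}
    for label in MARKER_LABELS:
        pos = series[label].copy()
        if hand_used == "left":
            pos[:, 0] *= -1.0
        if profile.noise_sd_mm > 0:
            pos += rng.normal(0.0, profile.noise_sd_mm, pos.shape)
        valid = np.ones(n_frames, dtype=bool)
        if label == "goal":
            valid[:goal_visible_frame] = False
            pos[:goal_visible_frame] = np.nan
        if profile.dropout_rate > 0 and label != "goal":
            f = 12
            while f < n_frames - 12:
                if rng.random() < profile.dropout_rate:
                    g = min(int(rng.geometric(0.35)), 8)
                    g = min(g, n_frames - 12 - f)
                    valid[f : f + g] = False
                    pos[f : f + g] = np.nan
                    f += g + 2
                else:
                    f += 1
        markers[label] = MarkerTrajectory(label, pos, valid, rate)

    rec = TrialRecording(
        markers=markers,
        goal_visible_frame=goal_visible_frame,
        condition=condition,
        hand=hand_used,
        group_label=profile.name,
        trial_id=trial_id,
    )
    return rec, gt


def simulate_cohort(
    profiles: dict[str, GroupProfile] | None = None,
    n_per_cell: int = 2,
    seed: int = 0,
    out_dir: str | Path | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
) -> tuple[list[tuple[TrialRecording, GroundTruth]], pd.DataFrame]:
    """Reproducible trial set across groups x conditions.

    Returns the trials plus a manifest (one row per trial linking the trial
    id — and the TSV file when ``out_dir`` is given — to its ground truth).
    The same seed always yields byte-identical files.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be at least 1")
    if profiles is None:
        profiles = default_profiles()
    trials: list[tuple[TrialRecording, GroundTruth]] = []
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for gi, (gname, prof) in enumerate(sorted(profiles.items())):
        for ci, cond in enumerate(conditions):
            for k in range(n_per_cell):
                ss = np.random.SeedSequence([seed, gi, ci, k])
                rng = np.random.default_rng(ss)
                tid = f"{gname}_{cond}_{k:03d}"
                rec, gt = simulate_trial(prof, cond, rng, trial_id=tid)
                trials.append((rec, gt))
                row = {
                    "trial_id": tid, "group": gname, "condition": cond,
                    "n_frames": gt.n_frames,
                    "true_latency_ms": gt.latency_ms,
                    "true_grasp_ms": gt.grasp_dwell_ms,
                    "true_onset_frame": gt.onset_frame,
                    "true_contact_frame": gt.contact_frame,
                    "true_lift_cross_frame": gt.lift_cross_frame,
                    "true_arrival_frame": gt.arrival_frame,
                    "true_return_cross_frame": gt.return_cross_frame,
                    "true_reach_mus": gt.reach_wrist_mus,
                    "true_transport_mus": gt.transport_wrist_mus,
                    "true_fitting_mus": gt.fitting_wrist_mus,
                    "true_rota1_ms": gt.rota1_ms,
                    "true_rota2_ms": gt.rota2_ms,
                    "true_residual_deg": gt.residual_angle_deg,
                }
                if out is not None:
                    fname = f"{tid}.tsv"
                    write_trial(rec, out / fname)
                    row["file"] = fname
                rows.append(row)
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return trials, manifest
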