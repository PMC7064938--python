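"""Phase segmentation of a reach-grasp-transport-fit trial.

The trial decomposes into four successive phases, each located by a
frame-based criterion on the smoothed marker data:

latency        : goal becomes visible -> wrist speed first reaches 20 mm/s
reach-to-grasp : from five frames before movement onset to five frames
                 after the wrist-speed low point at the end of the approach
                 that coincides with the peg markers starting to move
                 (object contact)
grasp          : from the approach low point to the frame where the peg has
                 risen 1 mm from its resting height (the five-frame
                 corrections on either side are excluded)
transport-to-fit: from five frames before the 1-mm peg lift to the frame
                 where the wrist, with the peg seated, first moves away
                 from the goal at 60 mm/s or faster (hand returning)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .kinematics import VelocityProfile
from .trial_io import MarkerTrajectory, TrialInvalidError


@dataclass
class PhaseBoundaries:
    goal_visible_frame: int
    movement_onset_frame: int
    reach_start_frame: int
    reach_end_frame: int
    transport_start_frame: int
    transport_end_frame: int
    contact_frame: int          # wrist-speed low point at object contact
    lift_frame: int             # peg risen 1 mm from its resting height
    rate_hz: float = 120.0
    flags: list[str] = field(default_factory=list)

    @property
    def latency_ms(self) -> float:
        return (
            (self.movement_onset_frame - self.goal_visible_frame)
            / self.rate_hz * 1000.0
        )

    @property
    def grasp_duration_ms(self) -> float:
        """Grasp interval with the two five-frame corrections excluded."""
        return (self.lift_frame - self.contact_frame) / self.rate_hz * 1000.0

    def to_dict(self) -> dict:
        d = {
            k: int(getattr(self, k))
            for k in (
                "goal_visible_frame", "movement_onset_frame",
                "reach_start_frame", "reach_end_frame",
                "transport_start_frame", "transport_end_frame",
                "contact_frame", "lift_frame",
            )
        }
        d["latency_ms"] = self.latency_ms
        d["grasp_duration_ms"] = self.grasp_duration_ms
        d["flags"] = list(self.flags)
        return d


def find_movement_onset(
    vp_wrist: VelocityProfile,
    goal_visible_frame: int,
    threshold_mm_s: float = 20.0,
    sustain_frames: int = 3,
) -> int:
    """First frame at or after goal visibility where wrist speed reaches
    the onset threshold and stays there.

    The sustain requirement rejects single-frame noise excursions of the
    filtered speed; a genuine movement onset rises monotonically through
    the threshold, so the detected frame is unbiased.
    """
    v = vp_wrist.v[goal_visible_frame:]
    k = max(1, sustain_frames)
    above = v >= threshold_mm_s
    for f in range(len(v) - k + 1):
        if (above[f : f + k].all()
                and np.max(v[f : f + 2 * k]) >= 1.5 * threshold_mm_s):
            return goal_visible_frame + f
    raise TrialInvalidError("wrist speed never reaches the onset threshold")


def _find_contact(
    vp_peg: VelocityProfile,
    wrist_pos: np.ndarray,
    peg_pos: np.ndarray,
    onset: int,
    cfg: AnalysisConfig,
) -> int:
    """Peak frame of the first peg-motion burst under the hand.

    Requires peg-centre speed above the contact threshold for a sustained
    run of frames while the wrist is within the contact radius of the peg,
    so that filtered marker noise or incidental peg jitter cannot fire the
    criterion before the hand is there.
    """
    v = vp_peg.v
    near = (
        np.linalg.norm(wrist_pos - peg_pos, axis=1) < cfg.contact_radius_mm
    )
    fast = v >= cfg.contact_speed_mm_s
    trigger = cfg.contact_trigger_factor * cfg.contact_speed_mm_s
    k = cfg.contact_sustain_frames
    f = onset + 1
    n = len(v)
    while f < n:
        if fast[f] and near[f]:
            j = f
            while j < n and fast[j]:
                j += 1
            # a genuine contact run is sustained and clearly exceeds the
            # threshold somewhere; filtered noise runs do neither.  The
            # first trigger-level crossing anchors the contact: zero-phase
            # smoothing spreads the run onset backward, and a short grasp
            # can merge the contact burst with the transport run, so
            # neither the run start nor its global peak is stable
            if j - f >= k and np.max(v[f:j]) >= trigger:
                return f + int(np.argmax(v[f:j] >= trigger))
            f = j
        else:
            f += 1
    raise TrialInvalidError("peg never moves: reach end undefined")


def find_reach_bounds(
    vp_wrist: VelocityProfile,
    vp_peg: VelocityProfile,
    onset_frame: int,
    wrist_pos: np.ndarray,
    peg_pos: np.ndarray,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[int, int, int]:
    """(reach_start, reach_end, contact_low_point).

    reach_start is five frames before movement onset.  The end of the
    approach is the wrist-speed low point immediately preceding the onset of
    peg motion (object contact); reach_end adds the five-frame correction so
    any final approach movement unit is retained in the reach phase.
    """
    c = cfg.boundary_correction_frames
    reach_start = max(0, onset_frame - c)
    anchor = _find_contact(vp_peg, wrist_pos, peg_pos, onset_frame, cfg)
    w0 = max(onset_frame, anchor - cfg.contact_window_frames - 2)
    # the wrist may still be decelerating when the peg-motion trigger
    # fires; allow the low point to fall just after the anchor
    w1 = min(anchor + 1, len(vp_wrist.v) - 1)
    v = vp_wrist.v
    # the approach low point: first frame at (or near) the window minimum.
    # Anchoring the window at the contact burst keeps dips between earlier
    # approach corrections out of reach, so any final movement unit stays
    # inside the reach phase
    vmin = float(np.min(v[w0 : w1 + 1]))
    eps = 0.5 * cfg.contact_speed_mm_s
    near_min = v[w0 : w1 + 1] <= vmin + eps
    # the hand's true stop is the final dip before the contact burst
    # ("including any final movement unit"): locate the last near-minimum
    # run and take its first local minimum (the frame the decline ends)
    prev = np.concatenate([[False], near_min[:-1]])
    entry = w0 + int(np.nonzero(near_min & ~prev)[0][-1])
    low = entry
    for f in range(entry, w1 + 1):
        if v[f] <= v[f - 1] and (f == len(v) - 1 or v[f] <= v[f + 1]):
            low = f
            break
    reach_end = min(low + c, len(v) - 1)
    return reach_start, reach_end, low


def find_transport_bounds(
    peg_center: MarkerTrajectory,
    vp_wrist: VelocityProfile,
    vp_peg: VelocityProfile,
    wrist_pos: np.ndarray,
    goal_xy: np.ndarray,
    contact_frame: int,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[int, int, int, list[str]]:
    """(transport_start, transport_end, lift_frame, flags).

    Transport starts five frames before the peg has risen 1 mm above its
    resting height (median height over the early grasp interval).  It ends
    when, with the peg seated in the goal slot, the wrist first moves away
    from the goal at the return-speed threshold; if the hand never returns
    the last frame is used and flagged.
    """
    flags: list[str] = []
    c = cfg.boundary_correction_frames
    z = peg_center.positions[:, 2]
    n = len(z)
    # resting height from the early grasp interval only: a short grasp may
    # already be lifting toward the end of a longer window
    base_hi = min(contact_frame + 6, n)
    baseline = float(np.median(z[contact_frame:base_hi]))
    lifted = np.nonzero(z[contact_frame:] >= baseline + cfg.lift_height_mm)[0]
    if len(lifted) == 0:
        raise TrialInvalidError("peg never lifts: transport undefined")
    lift = contact_frame + int(lifted[0])
    t_start = max(0, lift - c)

    # peg seated: inside the goal radius, at rest for a sustained run
    xy = peg_center.positions[:, :2]
    dist = np.linalg.norm(xy - goal_xy[None, :], axis=1)
    rest = vp_peg.v < cfg.peg_rest_speed_mm_s
    inside = dist < cfg.arrival_radius_mm
    k = cfg.peg_rest_frames
    seated = -1
    for f in range(lift, n - k + 1):
        if inside[f] and rest[f : f + k].all():
            seated = f + k - 1
            break
    if seated < 0:
        flags.append("peg never seated at goal")
        return t_start, n - 1, lift, flags

    # hand returning: sustained wrist speed >= threshold, with a genuine
    # outward radial velocity and the peg left at rest in the slot
    vw = vp_wrist.v
    v_xy = np.gradient(wrist_pos[:, :2], axis=0) * peg_center.rate_hz
    radial = wrist_pos[:, :2] - goal_xy[None, :]
    rnorm = np.linalg.norm(radial, axis=1, keepdims=True)
    radial = radial / np.where(rnorm > 1e-9, rnorm, 1.0)
    outward = (radial * v_xy).sum(axis=1) >= 0.5 * cfg.return_threshold_mm_s
    ks = cfg.return_sustain_frames
    t_end = -1
    for f in range(seated, n - ks + 1):
        if ((vw[f : f + ks] >= cfg.return_threshold_mm_s).all()
                and outward[f]
                and vp_peg.v[f] < cfg.peg_rest_speed_mm_s):
            t_end = f
            break
    if t_end < 0:
        flags.append("hand never returns")
        t_end = n - 1
    return t_start, t_end, lift, flags


def segment_trial(
    vp_wrist: VelocityProfile,
    vp_peg: VelocityProfile,
    wrist: MarkerTrajectory,
    peg_center: MarkerTrajectory,
    goal_xy: np.ndarray,
    goal_visible_frame: int,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> PhaseBoundaries:
    """Locate all phase boundaries of one trial."""
    onset = find_movement_onset(vp_wrist, goal_visible_frame,
                                cfg.onset_threshold_mm_s,
                                cfg.onset_sustain_frames)
    reach_start, reach_end, low = find_reach_bounds(
        vp_wrist, vp_peg, onset, wrist.positions, peg_center.positions, cfg
    )
    t_start, t_end, lift, flags = find_transport_bounds(
        peg_center, vp_wrist, vp_peg, wrist.positions, goal_xy, low, cfg
    )
    return PhaseBoundaries(
        goal_visible_frame=goal_visible_frame,
        movement_onset_frame=onset,
        reach_start_frame=reach_start,
        reach_end_frame=reach_end,
        transport_start_frame=t_start,
        transport_end_frame=t_end,
        contact_frame=low,
        lift_frame=lift,
        rate_hz=vp_wrist.rate_hz,
        flags=flags,
    )
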