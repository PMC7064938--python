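"""Peg-orientation analysis: angle extraction and Rota I / Rota II split.

The two flat markers on the peg top span a horizontal line; its angle to
the frontoparallel (x) axis, projected on the horizontal plane, is the peg
orientation.  Rotation accomplished while the peg travels to the goal
(Rota I) indexes pro-active planning of the required end orientation;
corrective rotation after arrival at the goal (Rota II) indexes reactive
adjustment.  The residual angle — how far the peg is from the goal
orientation at the moment of arrival — is the most direct planning marker:
an actor who rotated predictively arrives nearly aligned.

Angles are treated on the full circle (the semicircular peg fits its slot
in exactly one orientation); positive angles are counter-clockwise viewed
from above.  Round-peg trials carry no orientation demand and report a
residual of zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .config import AnalysisConfig, DEFAULT_CONFIG
from .trial_io import MarkerTrajectory, TrialInvalidError


@dataclass
class RotationProfile:
    theta: np.ndarray              # unwrapped peg angle per frame (deg)
    omega: np.ndarray              # smoothed angular speed (deg/s)
    goal_angle: float | None       # None for the round-peg condition
    arrival_frame: int
    rota1_duration_ms: float
    rota2_duration_ms: float
    residual_angle_deg: float

    @property
    def total_rotation_time_ms(self) -> float:
        return self.rota1_duration_ms + self.rota2_duration_ms


def fold_angle(delta_deg: float) -> float:
    """Fold an angle difference into [0, 180] degrees."""
    return abs((delta_deg + 180.0) % 360.0 - 180.0)


def peg_angle(
    peg_a: MarkerTrajectory,
    peg_b: MarkerTrajectory,
    span: tuple[int, int] | None = None,
    rezero_frames: int = 5,
) -> np.ndarray:
    """Unwrapped horizontal angle (deg) of the peg marker pair over span.

    The angle of (peg_b - peg_a) projected on the horizontal plane is
    unwrapped over time and re-zeroed on the start-holder orientation
    (median of the first ``rezero_frames`` frames), so the series reads as
    rotation accomplished since the start.  Swapping the marker identities
    offsets the raw angle by 180 degrees but leaves the re-zeroed series
    unchanged; marker identity is fixed at trial start.
    """
    lo, hi = (0, peg_a.n_frames - 1) if span is None else span
    delta = peg_b.positions[lo : hi + 1] - peg_a.positions[lo : hi + 1]
    planar = np.linalg.norm(delta[:, :2], axis=1)
    if np.any(planar < 1.0):
        raise TrialInvalidError("degenerate peg marker pair (< 1 mm in plane)")
    theta = np.unwrap(np.arctan2(delta[:, 1], delta[:, 0]))
    theta = np.degrees(theta)
    theta -= float(np.median(theta[: max(1, rezero_frames)]))
    return theta


def angular_speed(
    theta: np.ndarray,
    rate_hz: float,
    smooth_hz: float | None = 6.0,
    order: int = 2,
) -> np.ndarray:
    """Frame-wise angular speed (deg/s), optionally low-passed.

    Differentiating the marker-pair angle amplifies coordinate noise (the
    pair is only 20 mm apart), so a zero-phase low-pass on omega is applied
    before any thresholding.
    """
    omega = np.gradient(theta) * rate_hz
    if smooth_hz is not None and len(omega) > 15:
        b, a = butter(order, smooth_hz, fs=rate_hz)
        padlen = min(3 * (max(len(a), len(b)) - 1) * 4, len(omega) - 1)
        omega = filtfilt(b, a, omega, padlen=padlen)
    return omega


def detect_goal_arrival(
    peg_center: MarkerTrajectory,
    goal_xy: np.ndarray,
    span: tuple[int, int],
    arrival_radius_mm: float = 10.0,
) -> int:
    """First frame within span where the peg centre enters the goal radius."""
    if arrival_radius_mm <= 0:
        raise ValueError("arrival radius must be positive")
    lo, hi = span
    xy = peg_center.positions[lo : hi + 1, :2]
    dist = np.linalg.norm(xy - np.asarray(goal_xy)[None, :], axis=1)
    hits = np.nonzero(dist < arrival_radius_mm)[0]
    if len(hits) == 0:
        raise TrialInvalidError("peg never arrives at the goal")
    return lo + int(hits[0])


def _hysteresis(x: np.ndarray, low: float, high: float,
                min_run: int = 1) -> np.ndarray:
    """True on runs of x > low that contain a sample > high and last at
    least ``min_run`` samples."""
    above = x > low
    out = np.zeros_like(above)
    n = len(x)
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_run and np.any(x[i:j] > high):
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def _clip_to_angle_change(rotating: np.ndarray, theta: np.ndarray,
                          settle_deg: float = 0.5) -> np.ndarray:
    """Trim each rotating episode to where the angle demonstrably changes.

    The low-pass applied to angular speed stretches every rotation episode
    a few frames past its true boundaries.  The angle series itself is much
    sharper, so each episode is clipped to the span over which theta has
    departed from its pre-episode level and not yet settled at its
    post-episode level (a tolerance of ``settle_deg`` absorbs angle noise).
    Episodes with no net angle change (e.g. an out-and-back wobble) are
    left untouched.
    """
    out = rotating.copy()
    n = len(rotating)
    i = 0
    while i < n:
        if not rotating[i]:
            i += 1
            continue
        j = i
        while j < n and rotating[j]:
            j += 1
        a = max(0, i - 3)
        b = min(n, j + 3)
        th_a = float(np.median(theta[max(0, a - 4) : a + 1]))
        th_b = float(np.median(theta[b - 1 : min(n, b + 4)]))
        if abs(th_b - th_a) >= 4.0 * settle_deg:
            moved = np.abs(theta[i:j] - th_a) > settle_deg
            not_done = np.abs(th_b - theta[i:j]) > settle_deg
            out[i:j] &= moved & not_done
        i = j
    return out


def decompose_rotation(
    theta: np.ndarray,
    omega: np.ndarray,
    arrival_frame: int,
    transport_span: tuple[int, int],
    goal_angle: float | None,
    rate_hz: float,
    rotation_threshold_deg_s: float = 10.0,
    theta_offset: int = 0,
    trigger_factor: float = 3.0,
    min_run_frames: int = 4,
    settle_deg: float = 0.5,
) -> RotationProfile:
    """Split rotation time into transport (Rota I) and at-goal (Rota II).

    Rotation durations are the summed time of frames whose angular speed
    exceeds the threshold, before versus after arrival at the goal, within
    the transport span.  A hysteresis rule guards against marker noise:
    an above-threshold run is only counted when it contains at least one
    frame above ``trigger_factor`` times the threshold, a level genuine
    rotation episodes always reach but filtered angle noise does not.
    The residual angle compares the peg orientation at arrival with the
    goal orientation, folded to [0, 180]; round-peg trials report zero.
    """
    lo, hi = transport_span
    if not lo <= arrival_frame <= hi:
        raise ValueError("arrival frame outside transport span")
    i = slice(lo - theta_offset, hi + 1 - theta_offset)
    if i.start < 0 or i.stop > len(theta):
        raise ValueError("transport span outside angle series")
    th = theta[i]
    rotating = _hysteresis(np.abs(omega[i]), rotation_threshold_deg_s,
                           trigger_factor * rotation_threshold_deg_s,
                           min_run_frames)
    if settle_deg > 0:
        rotating = _clip_to_angle_change(rotating, th, settle_deg)
    k_arr = arrival_frame - lo
    dt = 1000.0 / rate_hz
    rota1 = float(rotating[:k_arr].sum() * dt)
    rota2 = float(rotating[k_arr:].sum() * dt)
    if goal_angle is None:
        residual = 0.0
    else:
        residual = fold_angle(theta[arrival_frame - theta_offset] - goal_angle)
    return RotationProfile(
        theta=theta,
        omega=omega,
        goal_angle=goal_angle,
        arrival_frame=arrival_frame,
        rota1_duration_ms=rota1,
        rota2_duration_ms=rota2,
        residual_angle_deg=residual,
    )
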