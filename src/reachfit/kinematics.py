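"""Velocity-domain features: tangential speed, movement units, segment metrics.

A movement unit (MU) is one acceleration-deceleration cycle of the speed
profile: a velocity peak whose accumulated rise from the preceding minimum
and fall to the following minimum both reach 20 mm/s, with frame-wise
acceleration or deceleration exceeding 5 mm/s^2 somewhere inside the unit.
MU count is the standard proxy for the number of corrective submovements in
a reach.  Sub-threshold peaks are merged into a neighbouring unit
(smallest-prominence first) before re-testing, which makes the segmentation
deterministic and monotone in the velocity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trial_io import MarkerTrajectory


@dataclass
class VelocityProfile:
    """Tangential speed (mm/s) and its frame-wise derivative (mm/s^2)."""

    v: np.ndarray
    a: np.ndarray
    rate_hz: float
    source_marker: str = ""

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if len(self.v) != len(self.a):
            raise ValueError("v and a must have equal length")
        if np.any(self.v < 0):
            raise ValueError("tangential speed cannot be negative")

    def __len__(self) -> int:
        return len(self.v)


@dataclass
class MovementUnit:
    start_frame: int
    peak_frame: int
    end_frame: int
    rise: float
    fall: float


@dataclass
class SegmentMetrics:
    duration_ms: float
    n_mus: int
    peak_velocity_mm_s: float
    time_of_peak_ms: float
    ppv_pct: float
    accel_phase_pct: float
    decel_phase_pct: float
    avg_velocity_mm_s: float
    path_distance_mm: float


def tangential_velocity(
    traj: MarkerTrajectory, span: tuple[int, int] | None = None
) -> VelocityProfile:
    """Speed along the path via central differences of smoothed positions.

    ``span`` is an inclusive frame interval (start, end); one-sided
    differences are used at its edges.  Differentiating positions (rather
    than filtering raw frame-to-frame differences) keeps the velocity
    consistent with the smoothed trajectory.
    """
    lo, hi = (0, traj.n_frames - 1) if span is None else span
    if hi - lo < 2:
        raise ValueError("span must cover at least 3 frames")
    pos = traj.positions[lo : hi + 1]
    if np.isnan(pos).any():
        raise ValueError("invalid frames inside span")
    vel = np.gradient(pos, axis=0) * traj.rate_hz
    v = np.linalg.norm(vel, axis=1)
    a = np.gradient(v) * traj.rate_hz
    return VelocityProfile(v=v, a=a, rate_hz=traj.rate_hz, source_marker=traj.label)


# ---------------------------------------------------------------------------
# Movement-unit detection
# ---------------------------------------------------------------------------

def _alternating_extrema(v: np.ndarray) -> tuple[list[int], list[int]]:
    """Interior extrema of v as alternating (minima, maxima) index lists.

    Plateaus are collapsed to their first frame.  Boundary frames are added
    as minima where needed so every candidate peak has two bounding minima;
    a truncated rise or fall at the span edge therefore never forms a unit
    on its own.
    """
    n = len(v)
    d = np.diff(v)
    sign = np.zeros(len(d), dtype=int)
    last = 0
    for i, x in enumerate(d):
        if x > 0:
            last = 1
        elif x < 0:
            last = -1
        sign[i] = last
    maxima: list[int] = []
    minima: list[int] = []
    for i in range(1, len(sign)):
        if sign[i - 1] > 0 and sign[i] < 0:
            maxima.append(i)
        elif sign[i - 1] < 0 and sign[i] > 0:
            minima.append(i)
    extrema = sorted([(i, "max") for i in maxima] + [(i, "min") for i in minima])
    # bracket peaks with boundary minima
    if extrema and extrema[0][1] == "max":
        extrema.insert(0, (0, "min"))
    if extrema and extrema[-1][1] == "max":
        extrema.append((n - 1, "min"))
    mins = [i for i, kind in extrema if kind == "min"]
    maxs = [i for i, kind in extrema if kind == "max"]
    return mins, maxs


def detect_movement_units(
    vp: VelocityProfile,
    min_delta_v: float = 20.0,
    min_accel: float = 5.0,
) -> list[MovementUnit]:
    """Segment a speed profile into movement units.

    The profile is partitioned at local minima; each candidate peak must
    rise at least ``min_delta_v`` from the preceding minimum and fall at
    least ``min_delta_v`` to the following one.  Failing peaks are merged
    into the neighbour across their higher bounding minimum, smallest
    prominence first (ties resolved toward the earlier neighbour), and the
    survivors are re-tested.  The acceleration clause (max |a| inside the
    unit >= ``min_accel``) acts as a final noise guard.
    """
    v = vp.v
    if len(v) == 0:
        return []
    mins, peaks = _alternating_extrema(v)
    # mins and peaks interleave as m0 < p0 < m1 < p1 ... < mk
    while peaks:
        proms = []
        for j, p in enumerate(peaks):
            rise = v[p] - v[mins[j]]
            fall = v[p] - v[mins[j + 1]]
            proms.append(min(rise, fall))
        failing = [j for j, pr in enumerate(proms) if pr < min_delta_v]
        if not failing:
            break
        j = min(failing, key=lambda k: (proms[k], k))
        if len(peaks) == 1:
            peaks.pop(j)
            break
        left_min, right_min = mins[j], mins[j + 1]
        can_left = j > 0
        can_right = j < len(peaks) - 1
        # merge across the higher bounding minimum; tie -> earlier neighbour
        if can_left and (not can_right or v[left_min] >= v[right_min]):
            # absorb into the left unit: drop the shared minimum and the
            # lower of the two peaks
            drop_peak = j if v[peaks[j]] <= v[peaks[j - 1]] else j - 1
            mins.pop(j)
            peaks.pop(drop_peak)
        else:
            drop_peak = j if v[peaks[j]] <= v[peaks[j + 1]] else j + 1
            mins.pop(j + 1)
            peaks.pop(drop_peak)
    units = []
    for j, p in enumerate(peaks):
        start, end = mins[j], mins[j + 1]
        if np.max(np.abs(vp.a[start : end + 1])) < min_accel:
            continue
        units.append(
            MovementUnit(
                start_frame=start,
                peak_frame=p,
                end_frame=end,
                rise=float(v[p] - v[start]),
                fall=float(v[p] - v[end]),
            )
        )
    return units


# ---------------------------------------------------------------------------
# Segment metrics
# ---------------------------------------------------------------------------

def segment_metrics(
    vp: VelocityProfile,
    traj: MarkerTrajectory,
    span: tuple[int, int],
    min_delta_v: float = 20.0,
    min_accel: float = 5.0,
    vp_offset: int = 0,
) -> SegmentMetrics:
    """Spatio-temporal parameters of one movement segment.

    ``span`` is an inclusive (start, end) frame interval in recording
    coordinates; ``vp_offset`` is the recording frame corresponding to
    ``vp.v[0]``.  Peak-velocity placement (PPV) is the position of the speed
    maximum as a percentage of segment duration; the acceleration and
    deceleration phases split the segment at the peak.
    """
    lo, hi = span
    if hi <= lo:
        raise ValueError("empty segment")
    i0, i1 = lo - vp_offset, hi - vp_offset
    if i0 < 0 or i1 >= len(vp):
        raise ValueError("span outside velocity profile")
    v = vp.v[i0 : i1 + 1]
    if np.all(v == 0):
        raise ValueError("all-zero speed: peak undefined")
    rate = vp.rate_hz
    peak = int(np.argmax(v))
    sub = VelocityProfile(v=v, a=vp.a[i0 : i1 + 1], rate_hz=rate,
                          source_marker=vp.source_marker)
    n_mus = len(detect_movement_units(sub, min_delta_v, min_accel))
    steps = np.diff(traj.positions[lo : hi + 1], axis=0)
    path = float(np.linalg.norm(steps, axis=1).sum())
    frames = hi - lo
    ppv = 100.0 * peak / frames
    return SegmentMetrics(
        duration_ms=frames / rate * 1000.0,
        n_mus=n_mus,
        peak_velocity_mm_s=float(v[peak]),
        time_of_peak_ms=peak / rate * 1000.0,
        ppv_pct=ppv,
        accel_phase_pct=ppv,
        decel_phase_pct=100.0 - ppv,
        avg_velocity_mm_s=float(v.mean()),
        path_distance_mm=path,
    )


def peak_time_difference(
    vp_index: VelocityProfile,
    vp_wrist: VelocityProfile,
    span: tuple[int, int],
    vp_offset: int = 0,
) -> float:
    """Index-minus-wrist peak-speed time (ms); negative = index peaks first."""
    lo, hi = span[0] - vp_offset, span[1] - vp_offset
    if lo < 0 or hi >= len(vp_index) or hi >= len(vp_wrist):
        raise ValueError("span outside velocity profiles")
    pi = int(np.argmax(vp_index.v[lo : hi + 1]))
    pw = int(np.argmax(vp_wrist.v[lo : hi + 1]))
    return (pi - pw) / vp_wrist.rate_hz * 1000.0
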