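"""Trial file format, gap repair and trajectory smoothing.

A trial is stored as a plain UTF-8 tab-separated file: comment-style header
lines carry the sampling rate and trial metadata, a column header names the
markers, and each subsequent row holds one frame.  A blank cell marks a
marker dropout for that frame; dropouts are carried through reading as an
explicit validity mask and are never silently interpolated.

Five markers are expected: ``wrist``, ``index``, the two peg-top markers
``peg_a``/``peg_b``, and the ``goal`` marker embedded in the goal holder
(whose first valid frame indicates when the goal became visible).
Coordinates are millimetres; x is the frontoparallel (left-right) axis,
y the sagittal/depth axis toward the goal, z vertical.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt

MARKER_LABELS = ("wrist", "index", "peg_a", "peg_b", "goal")
CONDITIONS = ("RP", "0", "90", "180", "-90")


class TrialFormatError(ValueError):
    """Raised when a trial file violates the TSV dialect."""


class TrialInvalidError(RuntimeError):
    """Raised when a trial cannot be analysed (e.g. unusable marker data)."""


@dataclass
class MarkerTrajectory:
    """One marker's 3D path.

    positions : (n, 3) float array, mm; NaN wherever ``valid`` is False.
    valid     : per-frame validity (False = dropout).
    imputed   : frames filled by :func:`gap_fill`.
    exclude_reason : set when the trajectory is unusable for analysis.
    """

    label: str
    positions: np.ndarray
    valid: np.ndarray
    rate_hz: float = 120.0
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]
    exclude_reason: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.valid) != len(self.positions):
            raise ValueError("positions and valid mask lengths differ")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.imputed is None:
            self.imputed = np.zeros(len(self.valid), dtype=bool)
        if not np.all(np.isfinite(self.positions[self.valid])):
            raise ValueError("non-finite coordinates on valid frames")

    @property
    def n_frames(self) -> int:
        return len(self.valid)

    def copy(self) -> "MarkerTrajectory":
        return MarkerTrajectory(
            label=self.label,
            positions=self.positions.copy(),
            valid=self.valid.copy(),
            rate_hz=self.rate_hz,
            imputed=self.imputed.copy(),
            exclude_reason=self.exclude_reason,
        )


@dataclass
class TrialRecording:
    """All marker trajectories plus metadata for one trial."""

    markers: dict[str, MarkerTrajectory]
    goal_visible_frame: int
    condition: str
    hand: str = "right"
    group_label: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        missing = set(MARKER_LABELS) - set(self.markers)
        if missing:
            raise TrialFormatError(f"missing markers: {sorted(missing)}")
        lengths = {m.n_frames for m in self.markers.values()}
        rates = {m.rate_hz for m in self.markers.values()}
        if len(lengths) != 1 or len(rates) != 1:
            raise TrialFormatError("markers disagree on frame count or rate")
        if self.condition not in CONDITIONS:
            raise TrialFormatError(f"condition must be one of {CONDITIONS}")
        if not 0 <= self.goal_visible_frame < self.n_frames:
            raise TrialFormatError("goal_visible_frame outside recording")
        if self.hand not in ("left", "right"):
            raise TrialFormatError("hand must be 'left' or 'right'")

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).n_frames

    @property
    def rate_hz(self) -> float:
        return next(iter(self.markers.values())).rate_hz

    @property
    def condition_angle(self) -> float | None:
        """Goal orientation in degrees; None for the round-peg condition."""
        return None if self.condition == "RP" else float(self.condition)

    def copy(self) -> "TrialRecording":
        return TrialRecording(
            markers={k: v.copy() for k, v in self.markers.items()},
            goal_visible_frame=self.goal_visible_frame,
            condition=self.condition,
            hand=self.hand,
            group_label=self.group_label,
            trial_id=self.trial_id,
        )


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def write_trial(recording: TrialRecording, path: str | Path) -> None:
    """Write a recording in the canonical TSV dialect (6-decimal mm)."""
    rate = recording.rate_hz
    n = recording.n_frames
    buf = io.StringIO()
    buf.write(f"#rate_hz={rate:g}\n")
    buf.write(f"#condition={recording.condition}\n")
    buf.write(f"#goal_visible_frame={recording.goal_visible_frame}\n")
    buf.write(f"#hand={recording.hand}\n")
    buf.write(f"#group={recording.group_label}\n")
    buf.write(f"#trial_id={recording.trial_id}\n")
    cols = ["frame", "t"]
    for label in MARKER_LABELS:
        cols += [f"{label}_{ax}" for ax in "xyz"]
    buf.write("\t".join(cols) + "\n")
    for i in range(n):
        cells = [str(i), f"{i / rate * 1000.0:.6f}"]
        for label in MARKER_LABELS:
            traj = recording.markers[label]
            if traj.valid[i]:
                cells += [f"{c:.6f}" for c in traj.positions[i]]
            else:
                cells += ["", "", ""]
        buf.write("\t".join(cells) + "\n")
    Path(path).write_text(buf.getvalue())


def read_trial(path: str | Path) -> TrialRecording:
    """Read a trial TSV file; blank cells become invalid frames."""
    lines = Path(path).read_text().splitlines()
    meta: dict[str, str] = {}
    idx = 0
    while idx < len(lines) and lines[idx].startswith("#"):
        key, _, value = lines[idx][1:].partition("=")
        meta[key.strip()] = value.strip()
        idx += 1
    if idx >= len(lines):
        raise TrialFormatError("no column header found")
    if "rate_hz" not in meta:
        raise TrialFormatError("missing #rate_hz header")
    header = lines[idx].split("\t")
    idx += 1
    expected = ["frame", "t"]
    for label in MARKER_LABELS:
        expected += [f"{label}_{ax}" for ax in "xyz"]
    if header != expected:
        raise TrialFormatError(
            f"unexpected column header (need {' '.join(expected)})"
        )
    ncol = len(expected)
    rows = [ln.split("\t") for ln in lines[idx:] if ln != ""]
    if any(len(r) != ncol for r in rows):
        raise TrialFormatError("inconsistent column counts")
    n = len(rows)
    rate = float(meta["rate_hz"])
    markers: dict[str, MarkerTrajectory] = {}
    for m, label in enumerate(MARKER_LABELS):
        pos = np.full((n, 3), np.nan)
        for i, r in enumerate(rows):
            cells = r[2 + 3 * m : 5 + 3 * m]
            if all(c != "" for c in cells):
                pos[i] = [float(c) for c in cells]
            elif any(c != "" for c in cells):
                raise TrialFormatError(
                    f"partially blank coordinates for {label} at frame {i}"
                )
        valid = ~np.isnan(pos).any(axis=1)
        markers[label] = MarkerTrajectory(label, pos, valid, rate)
    return TrialRecording(
        markers=markers,
        goal_visible_frame=int(meta.get("goal_visible_frame", 0)),
        condition=meta.get("condition", "RP"),
        hand=meta.get("hand", "right"),
        group_label=meta.get("group", ""),
        trial_id=meta.get("trial_id", ""),
    )


# ---------------------------------------------------------------------------
# Gap repair
# ---------------------------------------------------------------------------

def _gaps(valid: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of invalid frames as half-open [start, stop) pairs."""
    gaps = []
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            gaps.append((i, j))
            i = j
        else:
            i += 1
    return gaps


def gap_fill(
    traj: MarkerTrajectory,
    max_auto: int = 10,
    max_manual: int = 20,
    allow_manual: bool = False,
    span: tuple[int, int] | None = None,
) -> MarkerTrajectory:
    """Fill short interior dropouts by cubic-spline interpolation.

    Interior gaps of at most ``max_auto`` frames are filled automatically
    by monotone piecewise-cubic (PCHIP) interpolation;
    gaps up to ``max_manual`` frames are filled only when ``allow_manual``
    is set (the programmatic stand-in for accepting a gap after visual
    inspection).  Longer gaps, and edge gaps that cannot be anchored on both
    sides, are left invalid; gaps beyond ``max_manual`` inside the analysed
    span mark the trajectory as unusable.  Filled frames are recorded in the
    ``imputed`` mask.
    """
    if max_auto > max_manual:
        raise ValueError("max_auto must not exceed max_manual")
    out = traj.copy()
    lo, hi = (0, traj.n_frames) if span is None else span
    valid = out.valid
    if valid[lo:hi].all():
        return out
    idx = np.nonzero(valid)[0]
    idx = idx[(idx >= lo) & (idx < hi)]
    if len(idx) < 4:
        out.exclude_reason = "too few valid frames to interpolate"
        return out
    # shape-preserving piecewise-cubic interpolation: a global natural
    # spline rings on noisy anchor frames, a PCHIP cannot overshoot
    splines = [PchipInterpolator(idx, out.positions[idx, k])
               for k in range(3)]
    for start, stop in _gaps(valid):
        if stop <= lo or start >= hi:
            continue
        length = stop - start
        at_edge = start <= lo or stop >= hi
        if at_edge:
            if length > max_manual:
                out.exclude_reason = (
                    f"{length}-frame gap at recording edge (no anchor)"
                )
            continue
        fillable = length <= max_auto or (allow_manual and length <= max_manual)
        if fillable:
            frames = np.arange(start, stop)
            for k in range(3):
                out.positions[frames, k] = splines[k](frames)
            out.valid[frames] = True
            out.imputed[frames] = True
        elif length > max_manual:
            out.exclude_reason = f"{length}-frame gap exceeds manual limit"
    return out


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth(
    traj: MarkerTrajectory,
    cutoff_hz: float = 12.0,
    order: int = 2,
    span: tuple[int, int] | None = None,
) -> MarkerTrajectory:
    """Zero-phase low-pass (forward-backward Butterworth) per coordinate.

    The designed order applies to each pass; the forward-backward
    application doubles the effective order and cancels phase shift, so
    event timing is preserved.
    """
    if cutoff_hz >= traj.rate_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    out = traj.copy()
    lo, hi = (0, traj.n_frames) if span is None else span
    seg = out.positions[lo:hi]
    if np.isnan(seg).any():
        raise ValueError("invalid frames inside the analysed span; gap-fill first")
    b, a = butter(order, cutoff_hz, fs=traj.rate_hz)
    padlen = min(3 * (max(len(a), len(b)) - 1) * 4, len(seg) - 1)
    out.positions[lo:hi] = filtfilt(b, a, seg, axis=0, padlen=padlen)
    return out


def mirror_x(recording: TrialRecording) -> TrialRecording:
    """Reflect a recording about the mid-sagittal plane (negate x).

    Left-hand trials are mirrored before analysis so a single right-hand
    geometry serves both hands; the goal orientation angle changes sign
    under this reflection (handled in the pipeline).
    """
    out = recording.copy()
    for traj in out.markers.values():
        traj.positions[:, 0] *= -1.0
    return out
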