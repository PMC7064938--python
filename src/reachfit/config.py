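"""Analysis configuration.

All event-detection thresholds of the pipeline live here so that a study can
be re-analysed with one YAML file.  Defaults follow the protocol the package
implements: 120 Hz optoelectronic capture, 12 Hz second-order zero-phase
Butterworth smoothing, 20 mm/s movement-onset and movement-unit thresholds,
and the five-frame phase-boundary corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # trajectory repair / smoothing
    cutoff_hz: float = 12.0          # low-pass cutoff for marker smoothing
    filter_order: int = 2            # Butterworth design order (per pass)
    max_auto_gap: int = 10           # frames; gaps up to this are auto-filled
    max_manual_gap: int = 20         # frames; fillable only with allow_manual
    allow_manual: bool = False       # stand-in for visual gap-fill inspection

    # movement-onset / movement-unit thresholds
    onset_threshold_mm_s: float = 20.0
    onset_sustain_frames: int = 3
    mu_min_delta_v_mm_s: float = 20.0
    mu_min_accel_mm_s2: float = 5.0
    boundary_correction_frames: int = 5

    # reach-end (peg contact) operationalisation
    contact_speed_mm_s: float = 10.0   # peg-centre speed marking object contact
    contact_sustain_frames: int = 4    # minimum contact-run length (frames)
    contact_trigger_factor: float = 3.0  # run must peak above this multiple
    contact_window_frames: int = 10    # low point searched this far before contact
    contact_radius_mm: float = 80.0    # wrist must be this close to the peg

    # transport bounds
    lift_height_mm: float = 1.0        # upward peg travel defining transport onset
    return_threshold_mm_s: float = 60.0
    return_sustain_frames: int = 3
    peg_rest_speed_mm_s: float = 20.0  # peg considered seated below this speed
    peg_rest_frames: int = 6

    # rotation decomposition
    arrival_radius_mm: float = 10.0    # horizontal peg-goal distance at arrival
    rotation_threshold_deg_s: float = 10.0
    omega_smooth_hz: float = 6.0       # extra low-pass on angular speed
    rotation_trigger_factor: float = 3.0  # hysteresis trigger multiple
    rotation_min_frames: int = 4       # shortest countable episode
    rotation_settle_deg: float = 0.5   # angle-in-transit tolerance

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


DEFAULT_CONFIG = AnalysisConfig()
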