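"""Detection thresholds and YAML configuration round-trip.

The default thresholds are the ones used by the analysis this package
implements: saccades are velocity/amplitude-thresholded at 30 deg/s and 1 deg,
head movements at 6 deg/s and 3 deg, vertical saccades faster than
1000 deg/s peak are treated as blinks, saccades whose arc exceeds their chord
by more than 15 deg are flagged curved, and object fixations must fall within
1.24 deg (x) / 1.66 deg (y) of the object's screen position.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .geometry import ScreenGeometry

__all__ = ["DetectionConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds and algorithmic knobs for oculomotor event detection.

    All thresholds are strictly positive; angles in degrees, velocities in
    degrees per second.
    """

    saccade_vel_thresh: float = 30.0
    saccade_amp_thresh: float = 1.0
    head_vel_thresh: float = 6.0
    head_amp_thresh: float = 3.0
    blink_peak_vel_thresh: float = 1000.0
    curved_excess_thresh: float = 15.0
    object_tol_x: float = 1.24
    object_tol_y: float = 1.66

    #: Optional moving-average smoothing of position before differentiation,
    #: in samples (0 = off).  At 100 Hz with a 30 deg/s threshold raw central
    #: differences are adequate, so smoothing is disabled by default.
    smooth_window: int = 0
    #: Candidate velocity runs shorter than this many samples are discarded
    #: as unresolvable at the nominal sampling rate.
    min_run_samples: int = 2
    #: Runs separated by at most this many sub-threshold samples are merged.
    merge_gap_samples: int = 1
    #: A head movement counts as vestibulo-ocular only if the eye-in-head
    #: displacement over its interval opposes the head displacement and
    #: compensates at least this fraction of it.
    vor_min_compensation: float = 0.5
    #: Where the object position is evaluated when matching fixations:
    #: "onset" (at the fixation onset) or "min_distance" (closest approach
    #: within the fixation).
    match_at: str = "onset"

    def __post_init__(self) -> None:
        for name in (
            "saccade_vel_thresh",
            "saccade_amp_thresh",
            "head_vel_thresh",
            "head_amp_thresh",
            "blink_peak_vel_thresh",
            "curved_excess_thresh",
            "object_tol_x",
            "object_tol_y",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if self.match_at not in ("onset", "min_distance"):
            raise ConfigError(f"match_at must be 'onset' or 'min_distance', got {self.match_at!r}")
        if self.min_run_samples < 1:
            raise ConfigError("min_run_samples must be >= 1")


def save_config(path, cfg: DetectionConfig, geom: ScreenGeometry) -> None:
    """Write detection thresholds and screen geometry to a YAML file."""
    doc = {
        "geometry": dataclasses.asdict(geom),
        "detection": dataclasses.asdict(cfg),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def load_config(path) -> tuple[ScreenGeometry, DetectionConfig]:
    """Read a YAML configuration; missing keys fall back to the defaults."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        geom = ScreenGeometry(**doc.get("geometry", {}))
        cfg = DetectionConfig(**doc.get("detection", {}))
    except TypeError as exc:  # unknown key
        raise ConfigError(f"{path}: {exc}") from exc
    return geom, cfg
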