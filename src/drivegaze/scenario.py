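"""Scenario log: target objects, their screen-position tracks, and manual
responses (brake / turn indicator) recorded by the simulator.

Hazards (wild boars, coloured balls) approach the road from either side at
one of two eccentricities — "close" (10 m from the road) or "far" (30 m) —
while street signs and breakdown cars appear as non-moving roadside targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import FormatError, TrackCoverageError

__all__ = ["TargetObject", "ManualResponse", "ScenarioLog",
           "OBJECT_KINDS", "SIDES", "ECCENTRICITIES", "COURSES", "RESPONSE_CHANNELS"]

OBJECT_KINDS = ("boar", "ball", "sign", "breakdown_car")
SIDES = ("left", "right")
ECCENTRICITIES = ("close", "far")
COURSES = ("field", "ancient")  # easy vs. difficult course
RESPONSE_CHANNELS = ("brake", "indicator")


@dataclass
class TargetObject:
    """A scenario target with its time-indexed screen position in degrees."""

    id: str
    kind: str
    side: str
    eccentricity: str
    onset: float
    hazardous: bool
    track_t: np.ndarray = field(default_factory=lambda: np.empty(0))
    track_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    track_y: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.kind not in OBJECT_KINDS:
            raise FormatError(f"unknown object kind {self.kind!r} for object {self.id!r}")
        if self.side not in SIDES:
            raise FormatError(f"unknown side {self.side!r} for object {self.id!r}")
        if self.eccentricity not in ECCENTRICITIES:
            raise FormatError(f"unknown eccentricity {self.eccentricity!r} for object {self.id!r}")
        self.track_t = np.asarray(self.track_t, dtype=float)
        self.track_x = np.asarray(self.track_x, dtype=float)
        self.track_y = np.asarray(self.track_y, dtype=float)

    @property
    def track_end(self) -> float:
        if self.track_t.size == 0:
            return self.onset
        return float(self.track_t[-1])

    def position_at(self, t: float) -> tuple[float, float]:
        """Screen position (degrees) at time ``t``, linearly interpolated.

        Raises
        ------
        TrackCoverageError
            If the track is empty or does not cover ``t``.
        """
        if self.track_t.size == 0:
            raise TrackCoverageError(f"object {self.id!r} has no position track")
        if t < self.track_t[0] - 1e-9 or t > self.track_t[-1] + 1e-9:
            raise TrackCoverageError(
                f"object {self.id!r} track covers [{self.track_t[0]:.3f}, "
                f"{self.track_t[-1]:.3f}] s, position requested at {t:.3f} s"
            )
        x = float(np.interp(t, self.track_t, self.track_x))
        y = float(np.interp(t, self.track_t, self.track_y))
        return x, y

    def covers(self, t: float) -> bool:
        return self.track_t.size > 0 and self.track_t[0] - 1e-9 <= t <= self.track_t[-1] + 1e-9


@dataclass(frozen=True)
class ManualResponse:
    """A brake or turn-indicator press."""

    t: float
    channel: str

    def __post_init__(self) -> None:
        if self.channel not in RESPONSE_CHANNELS:
            raise FormatError(f"unknown response channel {self.channel!r}")


@dataclass
class ScenarioLog:
    """All objects and manual responses of one drive."""

    objects: list[TargetObject]
    responses: list[ManualResponse]
    course: str = "field"
    course_length_m: float = 6500.0

    def __post_init__(self) -> None:
        if self.course not in COURSES:
            raise FormatError(f"unknown course {self.course!r}")

    @property
    def n_hazardous(self) -> int:
        return sum(1 for o in self.objects if o.hazardous)
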