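"""Object-fixation matching and the two reaction-time modes.

For every target object two latencies are measured from its onset:

* *manual reaction*: the first brake or turn-indicator press inside the
  response window;
* *fixation reaction*: the onset of the earliest fixation whose centroid
  lies within the object tolerance box (|dx| <= 1.24 deg, |dy| <= 1.66 deg
  by default) around the object's screen position.

The *first-detection* reaction time is the smaller of the two: usually the
driver fixates the object first and reacts manually afterwards, but when the
manual response comes first it stands in as the moment of first detection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .config import DetectionConfig
from .events import Fixation
from .exceptions import AmbiguityWarning, InsufficientDataError, TrackCoverageError
from .scenario import ManualResponse, TargetObject

__all__ = ["ReactionRecord", "match_object_fixations", "reaction_times", "detection_rate"]


@dataclass
class ReactionRecord:
    """Per-object reaction outcome; latencies in milliseconds (NaN if absent)."""

    object_id: str
    kind: str
    eccentricity: str
    hazardous: bool
    onset: float
    rt_fixation_ms: float
    rt_manual_ms: float
    rt_first_detection_ms: float
    first_mode: str | None
    detected: bool


def match_object_fixations(
    fixations: list[Fixation],
    objects: list[TargetObject],
    cfg: DetectionConfig | None = None,
) -> dict[str, Fixation | None]:
    """Earliest qualifying fixation per object.

    A fixation qualifies when its onset is at or after the object onset,
    within the object's track span, and its centroid lies inside the
    tolerance box around the object position.  The object position is
    evaluated at the fixation onset (``cfg.match_at == "onset"``) or at the
    fixation's closest approach to the track (``"min_distance"``).

    Raises
    ------
    TrackCoverageError
        If an object's track does not cover its own onset.
    """
    cfg = cfg or DetectionConfig()
    fix_sorted = sorted(fixations, key=lambda f: f.onset)
    matches: dict[str, Fixation | None] = {}
    for obj in objects:
        if not obj.covers(obj.onset):
            raise TrackCoverageError(
                f"object {obj.id!r}: track does not cover its onset at {obj.onset:.3f} s"
            )
        found = None
        for fx in fix_sorted:
            if fx.onset < obj.onset or fx.onset > obj.track_end:
                continue
            if cfg.match_at == "onset":
                ox, oy = obj.position_at(fx.onset)
                inside = (
                    abs(fx.centroid_x - ox) <= cfg.object_tol_x
                    and abs(fx.centroid_y - oy) <= cfg.object_tol_y
                )
            else:  # closest approach of the track within the fixation
                t_hi = min(fx.offset, obj.track_end)
                ts = np.linspace(fx.onset, t_hi, max(2, int((t_hi - fx.onset) / 0.01) + 1))
                inside = False
                for tt in ts:
                    ox, oy = obj.position_at(float(tt))
                    if (
                        abs(fx.centroid_x - ox) <= cfg.object_tol_x
                        and abs(fx.centroid_y - oy) <= cfg.object_tol_y
                    ):
                        inside = True
                        break
            if inside:
                found = fx
                break
        matches[obj.id] = found
    return matches


def reaction_times(
    objects: list[TargetObject],
    matches: dict[str, Fixation | None],
    responses: list[ManualResponse],
    window: float = 10.0,
) -> list[ReactionRecord]:
    """Build per-object reaction records from fixation matches and responses.

    The response window runs from the object onset for ``window`` seconds or
    until the object's track ends, whichever comes first.  Each manual
    response is assigned to at most one object; when several object windows
    contain the same response an :class:`AmbiguityWarning` is emitted and the
    earlier-onset object takes it.
    """
    objs = sorted(objects, key=lambda o: o.onset)
    resp = sorted(responses, key=lambda r: r.t)
    windows = {o.id: (o.onset, o.onset + min(window, max(o.track_end - o.onset, 0.0))) for o in objs}
    used = [False] * len(resp)
    records: list[ReactionRecord] = []
    for obj in objs:
        w0, w1 = windows[obj.id]
        rt_manual = math.nan
        for k, r in enumerate(resp):
            if used[k] or r.t < w0:
                continue
            if r.t > w1:
                break
            used[k] = True
            rt_manual = (r.t - obj.onset) * 1000.0
            break
        fx = matches.get(obj.id)
        rt_fix = (fx.onset - obj.onset) * 1000.0 if fx is not None else math.nan
        candidates = [v for v in (rt_fix, rt_manual) if not math.isnan(v)]
        rt_first = min(candidates) if candidates else math.nan
        if not candidates:
            mode = None
        elif not math.isnan(rt_fix) and rt_fix <= rt_first:
            mode = "fixation_first"
        else:
            mode = "manual_first"
        records.append(
            ReactionRecord(
                object_id=obj.id,
                kind=obj.kind,
                eccentricity=obj.eccentricity,
                hazardous=obj.hazardous,
                onset=obj.onset,
                rt_fixation_ms=rt_fix,
                rt_manual_ms=rt_manual,
                rt_first_detection_ms=rt_first,
                first_mode=mode,
                detected=bool(candidates),
            )
        )
    # A response claimed by an earlier-onset object may have belonged to a
    # later object whose window overlaps; flag the genuinely ambiguous case
    # where that later object ended up without a manual response.
    for rec in records:
        if not math.isnan(rec.rt_manual_ms):
            continue
        w0, w1 = windows[rec.object_id]
        stolen = [r.t for k, r in enumerate(resp) if used[k] and w0 <= r.t <= w1]
        if stolen:
            warnings.warn(
                f"object {rec.object_id!r} has no manual response, but responses at "
                f"{[round(s, 3) for s in stolen]} s in its window were assigned to "
                "earlier-onset objects",
                AmbiguityWarning,
                stacklevel=2,
            )
    return records


def detection_rate(records: list[ReactionRecord]) -> float:
    """Fraction of objects detected by either mode."""
    if not records:
        raise InsufficientDataError("detection_rate needs at least one record")
    return sum(r.detected for r in records) / len(records)
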