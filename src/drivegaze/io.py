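"""Readers and writers for the package's plain-text dialects.

* Traces: comma-separated UTF-8, header ``t,eye_x,eye_y,head_x,head_y,valid``,
  times in seconds, angles in degrees, six decimal places.  A trace written
  and re-read is sample-identical at that precision.
* Scenarios: a file prefix expands to ``<prefix>_objects.csv``,
  ``<prefix>_track.csv``, ``<prefix>_responses.csv`` and ``<prefix>_meta.json``.
* Events: one tab-separated row per detected event with kind, timing,
  kinematic attributes and classification flags.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .scenario import ManualResponse, ScenarioLog, TargetObject
from .trace import GazeTrace

__all__ = [
    "load_trace",
    "save_trace",
    "load_scenario",
    "save_scenario",
    "write_events",
    "load_events",
    "events_to_frame",
]

_FLOAT_FMT = "%.6f"

_TRACE_REQUIRED = ("t", "eye_x", "eye_y", "head_x", "head_y", "valid")

EVENT_COLUMNS = (
    "kind",
    "onset",
    "offset",
    "duration",
    "amplitude",
    "arc_length",
    "peak_velocity",
    "curved",
    "offscreen",
    "blink",
    "vor_excluded",
)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def save_trace(trace: GazeTrace, path) -> None:
    """Write a trace as CSV (gaze columns are derived, hence not stored)."""
    df = pd.DataFrame(
        {
            "t": trace.t,
            "eye_x": trace.eye_x,
            "eye_y": trace.eye_y,
            "head_x": trace.head_x,
            "head_y": trace.head_y,
            "valid": trace.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_trace(path, geom=None) -> GazeTrace:
    """Read a trace CSV and return a validated :class:`GazeTrace`.

    Invalid samples are flagged, not dropped.  ``geom`` is accepted for
    interface symmetry with the writers but not needed to parse a trace.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in _TRACE_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    t = df["t"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +2: one for the header line, one for 0-based indexing.
        raise FormatError(f"{path}: time not strictly increasing at row {int(bad[0]) + 2}")
    return GazeTrace(
        t=t,
        eye_x=df["eye_x"].to_numpy(dtype=float),
        eye_y=df["eye_y"].to_numpy(dtype=float),
        head_x=df["head_x"].to_numpy(dtype=float),
        head_y=df["head_y"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _scenario_paths(prefix):
    prefix = Path(prefix)
    base = prefix.parent / prefix.name
    return (
        Path(f"{base}_objects.csv"),
        Path(f"{base}_track.csv"),
        Path(f"{base}_responses.csv"),
        Path(f"{base}_meta.json"),
    )


def save_scenario(log: ScenarioLog, prefix) -> None:
    """Write a scenario log under a path prefix (four sibling files)."""
    p_obj, p_trk, p_rsp, p_meta = _scenario_paths(prefix)
    pd.DataFrame(
        {
            "id": [o.id for o in log.objects],
            "kind": [o.kind for o in log.objects],
            "side": [o.side for o in log.objects],
            "eccentricity": [o.eccentricity for o in log.objects],
            "onset": [o.onset for o in log.objects],
            "hazardous": [int(o.hazardous) for o in log.objects],
        }
    ).to_csv(p_obj, index=False, float_format=_FLOAT_FMT)
    rows = []
    for o in log.objects:
        for tt, xx, yy in zip(o.track_t, o.track_x, o.track_y):
            rows.append((o.id, tt, xx, yy))
    pd.DataFrame(rows, columns=["object_id", "t", "x_deg", "y_deg"]).to_csv(
        p_trk, index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(
        {"t": [r.t for r in log.responses], "channel": [r.channel for r in log.responses]}
    ).to_csv(p_rsp, index=False, float_format=_FLOAT_FMT)
    p_meta.write_text(
        json.dumps({"course": log.course, "course_length_m": log.course_length_m}),
        encoding="utf-8",
    )


def load_scenario(prefix) -> ScenarioLog:
    """Read a scenario log written by :func:`save_scenario`."""
    p_obj, p_trk, p_rsp, p_meta = _scenario_paths(prefix)
    for p in (p_obj, p_trk, p_rsp, p_meta):
        if not p.exists():
            raise FormatError(f"scenario file missing: {p}")
    obj_df = pd.read_csv(p_obj, dtype={"id": str})
    trk_df = pd.read_csv(p_trk, dtype={"object_id": str})
    rsp_df = pd.read_csv(p_rsp)
    meta = json.loads(p_meta.read_text(encoding="utf-8"))
    objects = []
    grouped = dict(tuple(trk_df.groupby("object_id", sort=False)))
    for row in obj_df.itertuples(index=False):
        trk = grouped.get(row.id)
        if trk is None:
            tt = xx = yy = np.empty(0)
        else:
            tt = trk["t"].to_numpy(dtype=float)
            xx = trk["x_deg"].to_numpy(dtype=float)
            yy = trk["y_deg"].to_numpy(dtype=float)
        objects.append(
            TargetObject(
                id=row.id,
                kind=row.kind,
                side=row.side,
                eccentricity=row.eccentricity,
                onset=float(row.onset),
                hazardous=bool(row.hazardous),
                track_t=tt,
                track_x=xx,
                track_y=yy,
            )
        )
    responses = [
        ManualResponse(t=float(r.t), channel=str(r.channel)) for r in rsp_df.itertuples(index=False)
    ]
    return ScenarioLog(
        objects=objects,
        responses=responses,
        course=meta["course"],
        course_length_m=float(meta.get("course_length_m", 6500.0)),
    )


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def events_to_frame(events) -> pd.DataFrame:
    """Tabulate a list of detected events (saccades, fixations, head
    movements, VOR segments) into one row per event."""
    rows = []
    for ev in events:
        rows.append(
            {
                "kind": getattr(ev, "event_kind", type(ev).__name__.lower()),
                "onset": ev.onset,
                "offset": ev.offset,
                "duration": getattr(ev, "duration", ev.offset - ev.onset),
                "amplitude": getattr(ev, "amplitude", np.nan),
                "arc_length": getattr(ev, "arc_length", np.nan),
                "peak_velocity": getattr(ev, "peak_velocity", np.nan),
                "curved": int(getattr(ev, "curved", False)),
                "offscreen": int(getattr(ev, "offscreen", False)),
                "blink": int(getattr(ev, "blink", False)),
                "vor_excluded": int(getattr(ev, "vor_excluded", False)),
            }
        )
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def write_events(events, path) -> None:
    """Write events as a TSV table (header-only file for an empty list)."""
    frame = events if isinstance(events, pd.DataFrame) else events_to_frame(events)
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_events(path) -> pd.DataFrame:
    """Read an event table written by :func:`write_events`."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing event column(s): {', '.join(missing)}")
    return df
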