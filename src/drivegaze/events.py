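"""Oculomotor event detection and classification.

The gaze trajectory (eye-in-space = eye-in-head + head) is differentiated
with central differences and segmented into saccades by a velocity threshold
(30 deg/s) with a minimum chord amplitude (1 deg); everything between
retained saccades is a fixation.  Head movements are detected the same way
on the head channel (6 deg/s, 3 deg).  Classification follows three rules:

* *blink*: dominant-axis-vertical saccade with peak velocity above
  1000 deg/s — removed from the retained saccade list;
* *curved*: traversed arc exceeds the straight-line chord by more than
  15 deg — retained but flagged (curved saccades often directly precede
  object fixations, so discarding them would lose detections);
* *off-screen*: any gaze sample outside the screen rectangle, or touching a
  tracking-loss span — retained but flagged.

A head movement is excluded as vestibulo-ocular reflex (VOR) when the
eye-in-head counter-rotates against it over its interval, i.e. the movement
produces no gain in gaze amplitude.

Velocity thresholds are applied to combined gaze (eye + head), not
eye-in-head, because the quantity of interest is the gaze trajectory on the
screen.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DetectionConfig
from .exceptions import InsufficientDataError
from .geometry import ScreenGeometry
from .trace import GazeTrace

__all__ = [
    "Saccade",
    "Fixation",
    "HeadMovement",
    "VORSegment",
    "EventSet",
    "compute_velocity",
    "detect_saccades",
    "classify_saccade",
    "classify_saccades",
    "segment_fixations",
    "detect_head_movements",
    "detect_vor",
    "filter_head_movements",
    "main_sequence",
    "detect_events",
]

Velocity = namedtuple("Velocity", ["vx", "vy", "speed"])
MainSequenceResult = namedtuple("MainSequenceResult", ["table", "curved_fraction"])


# ---------------------------------------------------------------------------
# event types
# ---------------------------------------------------------------------------

@dataclass
class Saccade:
    """A velocity-thresholded gaze shift.

    ``amplitude`` is the chord (onset-to-offset displacement) of the gaze
    path, ``arc_length`` the summed inter-sample path length; the arc is
    never shorter than the chord.
    """

    onset: float
    offset: float
    i0: int
    i1: int
    amplitude: float
    arc_length: float
    peak_velocity: float
    duration: float
    direction: tuple[float, float]
    curved: bool = False
    offscreen: bool = False
    blink: bool = False

    event_kind = "saccade"

    @property
    def retained(self) -> bool:
        return not self.blink


@dataclass
class Fixation:
    """An inter-saccadic interval; centroid is the mean gaze position."""

    onset: float
    offset: float
    i0: int
    i1: int
    duration: float
    centroid_x: float
    centroid_y: float
    centroid_px: tuple[float, float] | None = None

    event_kind = "fixation"


@dataclass
class HeadMovement:
    onset: float
    offset: float
    i0: int
    i1: int
    amplitude: float
    arc_length: float
    peak_velocity: float
    duration: float
    direction: tuple[float, float]
    vor_excluded: bool = False

    event_kind = "head_movement"


@dataclass
class VORSegment:
    """A head movement whose gaze gain is cancelled by eye counter-rotation."""

    onset: float
    offset: float
    axis: str
    eye_direction: int
    head_direction: int

    event_kind = "vor"


@dataclass
class EventSet:
    """Everything detection produces for one trace."""

    saccades: list[Saccade]
    blinks: list[Saccade]
    fixations: list[Fixation]
    head_movements: list[HeadMovement]
    head_movements_filtered: list[HeadMovement]
    vor: list[VORSegment] = field(default_factory=list)


# ---------------------------------------------------------------------------
# velocity
# ---------------------------------------------------------------------------

def _channel_arrays(trace: GazeTrace, channel: str):
    if channel == "gaze":
        return trace.gaze_x, trace.gaze_y
    if channel == "eye":
        return trace.eye_x, trace.eye_y
    if channel == "head":
        return trace.head_x, trace.head_y
    raise ValueError(f"unknown channel {channel!r}")


def compute_velocity(trace: GazeTrace, channel: str = "gaze", smooth_window: int = 0) -> Velocity:
    """Central-difference velocity of a channel, in deg/s per axis.

    The velocity is defined at interior samples only and undefined (NaN) at
    samples that are invalid or adjacent to an invalid sample.  ``speed`` is
    the Euclidean norm of the axis velocities.

    Raises
    ------
    InsufficientDataError
        If the trace has fewer than 3 valid consecutive samples.
    """
    x, y = _channel_arrays(trace, channel)
    n = trace.n
    if n < 3:
        raise InsufficientDataError(f"need >= 3 samples to differentiate, got {n}")
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        x = np.convolve(x, kernel, mode="same")
        y = np.convolve(y, kernel, mode="same")
    t = trace.t
    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    denom = t[2:] - t[:-2]
    vx[1:-1] = (x[2:] - x[:-2]) / denom
    vy[1:-1] = (y[2:] - y[:-2]) / denom
    bad = ~trace.valid
    undef = bad.copy()
    undef[1:] |= bad[:-1]
    undef[:-1] |= bad[1:]
    vx[undef] = np.nan
    vy[undef] = np.nan
    speed = np.hypot(vx, vy)
    if np.count_nonzero(~np.isnan(speed)) == 0:
        raise InsufficientDataError("no interior samples with defined velocity")
    return Velocity(vx, vy, speed)


# ---------------------------------------------------------------------------
# run segmentation
# ---------------------------------------------------------------------------

def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask as inclusive (start, end) pairs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[k]), int(edges[k + 1]) - 1) for k in range(0, edges.size, 2)]


def _detect_movements(
    trace: GazeTrace,
    channel: str,
    vel_thresh: float,
    amp_thresh: float,
    cfg: DetectionConfig,
):
    """Shared threshold-run detector for gaze saccades and head movements.

    Candidate runs of supra-threshold speed are merged across single
    sub-threshold samples, short runs are discarded, and run boundaries are
    refined outward along strictly decreasing speed so that onset/offset land
    on the kinematic start/end of the movement rather than the threshold
    crossing.  Candidates whose chord does not exceed ``amp_thresh`` are
    discarded.
    """
    vel = compute_velocity(trace, channel, smooth_window=cfg.smooth_window)
    speed = vel.speed
    x, y = _channel_arrays(trace, channel)
    t = trace.t
    mask = speed > vel_thresh  # NaN compares False
    runs = _mask_runs(mask)

    # merge runs separated by <= merge_gap_samples sub-threshold samples
    merged: list[list[int]] = []
    for i0, i1 in runs:
        if merged and i0 - merged[-1][1] - 1 <= cfg.merge_gap_samples:
            gap = speed[merged[-1][1] + 1 : i0]
            if not np.isnan(gap).any():  # never merge across invalid spans
                merged[-1][1] = i1
                continue
        merged.append([i0, i1])

    events = []
    prev_end = -1
    for i0, i1 in merged:
        if i1 - i0 + 1 < cfg.min_run_samples:
            continue
        # boundary refinement: walk outward while speed keeps decreasing
        # (the floor keeps numerical dust from extending past the true rest)
        floor = 1e-6
        while i0 - 1 > prev_end and not np.isnan(speed[i0 - 1]) and floor < speed[i0 - 1] < speed[i0]:
            i0 -= 1
        while (
            i1 + 1 < trace.n - 1
            and not np.isnan(speed[i1 + 1])
            and floor < speed[i1 + 1] < speed[i1]
        ):
            i1 += 1
        dx = x[i1] - x[i0]
        dy = y[i1] - y[i0]
        chord = float(np.hypot(dx, dy))
        if chord <= amp_thresh:
            continue
        seg_x = x[i0 : i1 + 1]
        seg_y = y[i0 : i1 + 1]
        arc = float(np.sum(np.hypot(np.diff(seg_x), np.diff(seg_y))))
        peak = float(np.nanmax(speed[i0 : i1 + 1]))
        events.append(
            dict(
                onset=float(t[i0]),
                offset=float(t[i1]),
                i0=i0,
                i1=i1,
                amplitude=chord,
                arc_length=max(arc, chord),
                peak_velocity=peak,
                duration=float(t[i1] - t[i0]),
                direction=(dx / chord, dy / chord),
            )
        )
        prev_end = i1
    return events


def detect_saccades(trace: GazeTrace, cfg: DetectionConfig | None = None) -> list[Saccade]:
    """Detect candidate saccades on the combined gaze channel.

    Returns every candidate exceeding the velocity and amplitude thresholds;
    classification (blink removal, curved / off-screen flags) is a separate
    step, see :func:`classify_saccades`.
    """
    cfg = cfg or DetectionConfig()
    raw = _detect_movements(trace, "gaze", cfg.saccade_vel_thresh, cfg.saccade_amp_thresh, cfg)
    return [Saccade(**r) for r in raw]


def detect_head_movements(trace: GazeTrace, cfg: DetectionConfig | None = None) -> list[HeadMovement]:
    """Detect head movements (6 deg/s velocity, 3 deg amplitude by default)."""
    cfg = cfg or DetectionConfig()
    raw = _detect_movements(trace, "head", cfg.head_vel_thresh, cfg.head_amp_thresh, cfg)
    return [HeadMovement(**r) for r in raw]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_saccade(
    s: Saccade,
    trace: GazeTrace,
    cfg: DetectionConfig,
    geom: ScreenGeometry | None = None,
) -> dict[str, bool]:
    """Set the blink / curved / off-screen flags of one saccade.

    * blink: dominant axis vertical (|dy| > |dx|) and peak velocity above the
      blink threshold;
    * curved: arc length exceeds the chord by more than the curved-excess
      threshold (absolute degrees);
    * off-screen: any gaze sample outside the screen rectangle, or the
      saccade touches a tracking-loss span.
    """
    ux, uy = s.direction
    vertical = abs(uy) > abs(ux)
    s.blink = bool(vertical and s.peak_velocity > cfg.blink_peak_vel_thresh)
    s.curved = bool(s.arc_length - s.amplitude > cfg.curved_excess_thresh)
    # a 2-sample halo: runs are truncated two samples before a lost-signal
    # span because the central-difference velocity is undefined next to it
    lo = max(s.i0 - 2, 0)
    hi = min(s.i1 + 2, trace.n - 1)
    offscreen = bool(not trace.valid[lo : hi + 1].all())
    if geom is not None and not offscreen:
        gx = trace.gaze_x[s.i0 : s.i1 + 1]
        gy = trace.gaze_y[s.i0 : s.i1 + 1]
        offscreen = bool(not geom.contains_deg(gx, gy).all())
    s.offscreen = offscreen
    return {"blink": s.blink, "curved": s.curved, "offscreen": s.offscreen}


def classify_saccades(
    saccades: list[Saccade],
    trace: GazeTrace,
    cfg: DetectionConfig,
    geom: ScreenGeometry | None = None,
) -> tuple[list[Saccade], list[Saccade]]:
    """Classify all saccades; returns ``(retained, blinks)``.

    Blinks are removed from the retained list; curved and off-screen saccades
    stay, flagged.
    """
    for s in saccades:
        classify_saccade(s, trace, cfg, geom)
    retained = [s for s in saccades if not s.blink]
    blinks = [s for s in saccades if s.blink]
    return retained, blinks


# ---------------------------------------------------------------------------
# fixations
# ---------------------------------------------------------------------------

def segment_fixations(
    trace: GazeTrace,
    saccades: list[Saccade],
    geom: ScreenGeometry | None = None,
    exclude: list[Saccade] | None = None,
) -> list[Fixation]:
    """Sections between retained saccades, within valid spans of the trace.

    Fixations and retained saccades share their boundary samples, so their
    durations tile the valid trace time exactly.  Events in ``exclude``
    (typically blinks, which are artifacts rather than gaze) keep their time
    inside the surrounding fixation but their samples are left out of the
    centroid.
    """
    artifact = np.zeros(trace.n, dtype=bool)
    for ev in exclude or ():
        artifact[ev.i0 : ev.i1 + 1] = True
    fixations: list[Fixation] = []
    sac_sorted = sorted(saccades, key=lambda s: s.i0)
    for a, b in _mask_runs(trace.valid):
        if b <= a:
            continue
        bounds = [a]
        for s in sac_sorted:
            if s.i0 >= a and s.i1 <= b:
                bounds.extend((s.i0, s.i1))
        bounds.append(b)
        for k in range(0, len(bounds), 2):
            ia, ib = bounds[k], bounds[k + 1]
            if ib <= ia:
                continue
            keep = ~artifact[ia : ib + 1]
            if not keep.any():
                keep = np.ones(ib - ia + 1, dtype=bool)
            cx = float(np.mean(trace.gaze_x[ia : ib + 1][keep]))
            cy = float(np.mean(trace.gaze_y[ia : ib + 1][keep]))
            cpx = None
            if geom is not None:
                px, py = geom.deg_to_px(cx, cy)
                cpx = (float(px), float(py))
            fixations.append(
                Fixation(
                    onset=float(trace.t[ia]),
                    offset=float(trace.t[ib]),
                    i0=ia,
                    i1=ib,
                    duration=float(trace.t[ib] - trace.t[ia]),
                    centroid_x=cx,
                    centroid_y=cy,
                    centroid_px=cpx,
                )
            )
    return fixations


# ---------------------------------------------------------------------------
# VOR
# ---------------------------------------------------------------------------

def detect_vor(
    trace: GazeTrace,
    head_movements: list[HeadMovement],
    cfg: DetectionConfig | None = None,
) -> list[VORSegment]:
    """Mark head movements cancelled by simultaneous eye counter-rotation.

    Over each head movement's interval the eye-in-head displacement on the
    dominant head axis is compared with the head displacement: opposite sign
    and at least ``cfg.vor_min_compensation`` of its magnitude means the
    movement contributed no gaze amplitude and is excluded as VOR.  The
    ``vor_excluded`` flag is set in place; the returned segments describe the
    excluded intervals.
    """
    cfg = cfg or DetectionConfig()
    segments: list[VORSegment] = []
    for hm in head_movements:
        dhx = trace.head_x[hm.i1] - trace.head_x[hm.i0]
        dhy = trace.head_y[hm.i1] - trace.head_y[hm.i0]
        if abs(dhx) >= abs(dhy):
            axis, head_disp = "x", dhx
            eye_disp = trace.eye_x[hm.i1] - trace.eye_x[hm.i0]
        else:
            axis, head_disp = "y", dhy
            eye_disp = trace.eye_y[hm.i1] - trace.eye_y[hm.i0]
        opposite = eye_disp * head_disp < 0
        compensating = abs(eye_disp) >= cfg.vor_min_compensation * abs(head_disp)
        hm.vor_excluded = bool(opposite and compensating)
        if hm.vor_excluded:
            segments.append(
                VORSegment(
                    onset=hm.onset,
                    offset=hm.offset,
                    axis=axis,
                    eye_direction=int(np.sign(eye_disp)),
                    head_direction=int(np.sign(head_disp)),
                )
            )
    return segments


def filter_head_movements(
    head_movements: list[HeadMovement],
    vor: list[VORSegment] | None = None,
) -> list[HeadMovement]:
    """Head movements that survive VOR exclusion (never more than the input)."""
    return [hm for hm in head_movements if not hm.vor_excluded]


# ---------------------------------------------------------------------------
# main sequence
# ---------------------------------------------------------------------------

def main_sequence(saccades: list[Saccade]) -> MainSequenceResult:
    """Amplitude / peak-velocity / duration table of the retained saccades.

    Also reports the fraction of curved saccades; for an empty input the
    table is empty and the fraction undefined (NaN).
    """
    table = pd.DataFrame(
        {
            "amplitude": [s.amplitude for s in saccades],
            "peak_velocity": [s.peak_velocity for s in saccades],
            "duration": [s.duration for s in saccades],
            "curved": [s.curved for s in saccades],
            "offscreen": [s.offscreen for s in saccades],
        }
    )
    if len(saccades) == 0:
        return MainSequenceResult(table, float("nan"))
    frac = float(np.mean(table["curved"].to_numpy()))
    return MainSequenceResult(table, frac)


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------

def detect_events(
    trace: GazeTrace,
    cfg: DetectionConfig | None = None,
    geom: ScreenGeometry | None = None,
) -> EventSet:
    """Full detection pass: saccades, blinks, fixations, head movements, VOR."""
    cfg = cfg or DetectionConfig()
    candidates = detect_saccades(trace, cfg)
    retained, blinks = classify_saccades(candidates, trace, cfg, geom)
    fixations = segment_fixations(trace, retained, geom, exclude=blinks)
    heads = detect_head_movements(trace, cfg)
    vor = detect_vor(trace, heads, cfg)
    return EventSet(
        saccades=retained,
        blinks=blinks,
        fixations=fixations,
        head_movements=heads,
        head_movements_filtered=filter_head_movements(heads, vor),
        vor=vor,
    )
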