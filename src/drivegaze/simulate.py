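"""Synthetic gaze/head traces, scenario logs, and cohort tables with known
ground truth.

The generator emulates one drive through the simulator scenario: gaze
alternates between fixations and minimum-jerk saccades whose peak velocity
follows a saturating main-sequence law ``v(A) = v_max * (1 - exp(-A/scale))``
exactly (before measurement noise).  Gaze shifts larger than a configurable
threshold recruit the head, which carries the excess amplitude with a short
lag while the eye counter-rotates to keep gaze on target once the saccade
has landed.  Scripted vestibulo-ocular episodes (head turn with compensating
eye counter-rotation and zero gaze gain), blinks (fast vertical excursions
with peak velocity above 1000 deg/s), and curved saccades (circular-arc gaze
paths whose arc exceeds the chord by more than 15 deg) exercise every
classification rule of the detection stage.

Target objects follow the hazard schedule of the driving task: by default
eight hazardous events per course — two wild boars and two coloured balls
per side of the road, at two eccentricities — plus roadside signs and
breakdown cars.  Per object the generator scripts a fixation latency (with
the configured eccentricity/course effects) and a manual response at a fixed
motor delay after it, so the two reaction-time modes have exact ground
truth; a configurable fraction of objects is answered manually *before*
fixation.

Everything is reproducible from the configuration seed alone.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import DetectionConfig
from .exceptions import ConfigError, InsufficientDataError
from .geometry import ScreenGeometry
from .io import save_scenario, save_trace
from .scenario import ManualResponse, ScenarioLog, TargetObject
from .trace import GazeTrace

__all__ = [
    "GeneratorConfig",
    "SubjectAttributes",
    "GroundTruth",
    "generate_scenario",
    "generate_subject",
    "generate_cohort",
    "generate_cohort_table",
    "MANUAL_RT_EFFECTS",
    "evaluate_detection",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one simulated drive.

    Defaults reproduce the experiment's structure: 100 Hz sampling, a course
    of roughly ten minutes, eight hazardous events (boars and balls, two per
    side at two eccentricities) plus roadside signs/cars, and reaction-time
    effects taken from the study's first-detection model with a 300 ms motor
    delay on top for the manual response.
    """

    seed: int = 0
    sample_rate: float = 100.0
    duration_s: float = 600.0
    course: str = "field"

    # scenario schedule
    n_hazard_events: int = 8
    n_signs_cars: int = 4
    schedule_margin_s: float = 8.0
    object_drift_deg_s: float = 0.4
    track_length_s: float = 12.0

    # main-sequence law: peak velocity = v_max * (1 - exp(-A / ms_scale))
    v_max: float = 500.0
    ms_scale: float = 14.0

    # background saccade amplitudes (deg): amp_min + Gamma(shape, scale), capped
    amp_min: float = 1.5
    amp_gamma_shape: float = 2.0
    amp_gamma_scale: float = 3.0
    amp_max: float = 28.0

    # fixation durations (s)
    fix_dur_mean_s: float = 0.45
    fix_dur_min_s: float = 0.30
    fix_dur_max_s: float = 0.90

    # eye-head coordination
    head_contribution_threshold: float = 20.0
    head_min_amplitude: float = 3.5
    head_lag_s: float = 0.05

    # episodic events
    vor_rate_per_min: float = 2.0
    blink_rate_per_min: float = 6.0
    curved_fraction: float = 0.029

    # measurement noise (deg, added last; gaze stays the derived sum)
    position_noise_sd: float = 0.1
    head_noise_sd: float = 0.02

    # reaction latencies (ms)
    fix_latency_base_ms: float = 874.4
    fix_latency_ecc_ms: float = 1243.6
    fix_latency_course_ms: float = -187.0
    fix_latency_ecc_course_ms: float = 853.0
    motor_delay_ms: float = 300.0
    rt_noise_sd_ms: float = 100.0
    subject_rt_sd_ms: float = 0.0
    manual_first_prob: float = 0.05
    manual_first_advance_ms: float = 150.0
    object_hold_s: float = 0.6

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.duration_s <= 0:
            raise ConfigError("sample_rate and duration_s must be positive")
        if self.v_max <= 0 or self.ms_scale <= 0:
            raise ConfigError("main-sequence parameters must be positive")
        if not (0 <= self.curved_fraction < 1):
            raise ConfigError("curved_fraction must be in [0, 1)")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def peak_velocity(self, amplitude: float) -> float:
        """The configured main-sequence law."""
        return self.v_max * (1.0 - math.exp(-amplitude / self.ms_scale))


@dataclass
class SubjectAttributes:
    """Covariates of one simulated participant."""

    subject_id: str = "s01"
    age: float = 45.0
    vg_group: str = "minimum"   # minimum / moderate / extensive
    gender: str = "male"
    driving_experience: float = 20.0
    malaise: str = "no"
    rt_shift_ms: float = 0.0    # subject-level random intercept on latencies


@dataclass
class GroundTruth:
    """True event timeline and per-object latencies of a generated trace."""

    saccades: pd.DataFrame
    head_movements: pd.DataFrame
    vor: pd.DataFrame
    blinks: pd.DataFrame
    objects: pd.DataFrame
    subject: SubjectAttributes = field(default_factory=SubjectAttributes)


# ---------------------------------------------------------------------------
# kinematic primitives
# ---------------------------------------------------------------------------

def _minjerk(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau * tau)


def _saccade_duration(cfg: GeneratorConfig, amplitude: float) -> tuple[float, float]:
    """Duration and analytic peak velocity of a min-jerk saccade obeying the
    main-sequence law (peak of a min-jerk profile is 1.875 A / D)."""
    v = cfg.peak_velocity(amplitude)
    return 1.875 * amplitude / v, v


def _head_peak_velocity(amplitude: float) -> float:
    return min(120.0, 20.0 + 4.0 * amplitude)


def _head_duration(amplitude: float) -> tuple[float, float]:
    v = _head_peak_velocity(amplitude)
    return 1.875 * amplitude / v, v


class _ChannelWriter:
    """Writes chronological min-jerk motions into a sampled position array,
    holding the last position between motions."""

    def __init__(self, t: np.ndarray, x0: float, y0: float):
        self.t = t
        self.dt = float(t[1] - t[0])
        self.x = np.empty_like(t)
        self.y = np.empty_like(t)
        self.fill = 0
        self.cur = np.array([x0, y0], dtype=float)

    def _fill_to(self, idx: int) -> None:
        idx = min(idx, self.t.size)
        if idx > self.fill:
            self.x[self.fill : idx] = self.cur[0]
            self.y[self.fill : idx] = self.cur[1]
            self.fill = idx

    def line(self, t_start: float, duration: float, target) -> None:
        """Min-jerk straight movement from the current position to target."""
        k0 = int(math.ceil(t_start / self.dt - 1e-9))
        kend = int(math.ceil((t_start + duration) / self.dt - 1e-9))
        self._fill_to(k0)
        k0 = max(k0, 0)
        kend = min(kend, self.t.size - 1)
        if kend >= k0:
            tau = (self.t[k0 : kend + 1] - t_start) / duration
            s = _minjerk(tau)
            p0 = self.cur.copy()
            d = np.asarray(target, dtype=float) - p0
            self.x[k0 : kend + 1] = p0[0] + d[0] * s
            self.y[k0 : kend + 1] = p0[1] + d[1] * s
            self.fill = kend + 1
        self.cur = np.asarray(target, dtype=float)

    def arc(self, t_start: float, duration: float, target, arc_length: float, side: int) -> None:
        """Min-jerk movement along a circular arc of the given length."""
        p0 = self.cur.copy()
        p1 = np.asarray(target, dtype=float)
        chord = float(np.hypot(*(p1 - p0)))
        ratio = arc_length / chord
        theta = brentq(lambda th: th / (2.0 * math.sin(th / 2.0)) - ratio, 1e-6, 2.0 * math.pi - 1e-9)
        radius = chord / (2.0 * math.sin(theta / 2.0))
        mid = (p0 + p1) / 2.0
        u = (p1 - p0) / chord
        perp = np.array([-u[1], u[0]])
        h = radius * math.cos(theta / 2.0)
        center = mid + side * h * perp
        phi0 = math.atan2(p0[1] - center[1], p0[0] - center[0])
        phi1 = math.atan2(p1[1] - center[1], p1[0] - center[0])
        d = (phi1 - phi0 + math.pi) % (2.0 * math.pi) - math.pi
        cands = [d, d - 2.0 * math.pi * np.sign(d or 1.0)]
        sweep = min(cands, key=lambda s: abs(abs(s) - theta))
        k0 = int(math.ceil(t_start / self.dt - 1e-9))
        kend = int(math.ceil((t_start + duration) / self.dt - 1e-9))
        self._fill_to(k0)
        kend = min(kend, self.t.size - 1)
        if kend >= k0:
            tau = (self.t[k0 : kend + 1] - t_start) / duration
            phi = phi0 + sweep * _minjerk(tau)
            self.x[k0 : kend + 1] = center[0] + radius * np.cos(phi)
            self.y[k0 : kend + 1] = center[1] + radius * np.sin(phi)
            # land exactly on the target at the final sample
            self.x[kend] = p1[0]
            self.y[kend] = p1[1]
            self.fill = kend + 1
        self.cur = p1

    def finish(self) -> None:
        self._fill_to(self.t.size)


# ---------------------------------------------------------------------------
# scenario
# ---------------------------------------------------------------------------

def _max_latency_s(cfg: GeneratorConfig) -> float:
    lat = (
        cfg.fix_latency_base_ms
        + max(cfg.fix_latency_ecc_ms, 0.0)
        + max(cfg.fix_latency_course_ms, 0.0)
        + max(cfg.fix_latency_ecc_course_ms, 0.0)
        + 3.5 * cfg.rt_noise_sd_ms
        + 3.0 * cfg.subject_rt_sd_ms
        + cfg.motor_delay_ms
    )
    return lat / 1000.0


def _slot_min_s(cfg: GeneratorConfig) -> float:
    # latency + object hold + settling room for surrounding fixations
    return _max_latency_s(cfg) + cfg.object_hold_s + 1.9


def generate_scenario(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> ScenarioLog:
    """Build the object schedule of one course (no responses yet).

    The default configuration emits exactly eight hazardous events: the full
    crossing of {boar, ball} x {left, right} x {close, far}.

    Raises
    ------
    ConfigError
        If the requested number of events cannot be scheduled with enough
        separation inside ``duration_s`` (infeasible schedule).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    hazard_combos = list(product(("boar", "ball"), ("left", "right"), ("close", "far")))
    hazards = [hazard_combos[i % len(hazard_combos)] for i in range(cfg.n_hazard_events)]
    others = [
        (("sign", "breakdown_car")[i % 2], ("left", "right")[(i // 2) % 2], ("close", "far")[i % 2])
        for i in range(cfg.n_signs_cars)
    ]
    specs = [(k, s, e, True) for k, s, e in hazards] + [(k, s, e, False) for k, s, e in others]
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]

    n_events = len(specs)
    t0 = cfg.schedule_margin_s
    t1 = cfg.duration_s - cfg.schedule_margin_s
    slot_min = _slot_min_s(cfg)
    if n_events:
        slot = (t1 - t0) / n_events
        if slot < slot_min or t1 <= t0:
            raise ConfigError(
                f"infeasible schedule: {n_events} events need >= {n_events * slot_min + 2 * cfg.schedule_margin_s:.0f} s, "
                f"duration_s is {cfg.duration_s:.0f} s"
            )
    objects = []
    dt = cfg.dt
    for i, (kind, side, ecc, hazardous) in enumerate(specs):
        onset = t0 + i * slot + rng.uniform(0.0, max(slot - slot_min, 0.0))
        onset = round(onset / dt) * dt
        sign = -1.0 if side == "left" else 1.0
        x0 = sign * ((8.0 if ecc == "close" else 16.0) + rng.uniform(-1.5, 1.5))
        y0 = -4.0 + rng.uniform(-1.0, 1.0)
        tau = np.arange(0.0, cfg.track_length_s + 1e-9, 0.2)
        absx = np.maximum(3.5, abs(x0) - cfg.object_drift_deg_s * tau)
        objects.append(
            TargetObject(
                id=f"obj{i:02d}",
                kind=kind,
                side=side,
                eccentricity=ecc,
                onset=onset,
                hazardous=hazardous,
                track_t=onset + tau,
                track_x=np.sign(x0) * absx,
                track_y=np.full_like(tau, y0),
            )
        )
    return ScenarioLog(objects=objects, responses=[], course=cfg.course)


# ---------------------------------------------------------------------------
# one subject
# ---------------------------------------------------------------------------

_GAZE_BOX = (-24.0, 24.0, -16.0, 12.0)  # x_lo, x_hi, y_lo, y_hi (deg)
_AVOID_DEG = 3.0                        # keep background targets off pending tracks
_BLINK_AMPLITUDE = 30.0
_BLINK_MOVE_S = 0.04
_BLINK_PAUSE_S = 0.03
_VOR_PAUSE_S = 0.2
_SCRIPT_GUARD_S = 0.25                  # upper bound on a scripted saccade duration
_SETTLE_S = 1.2                         # background action + trailing fixation room


def _track_min_distance(point: np.ndarray, obj: TargetObject) -> float:
    d = np.hypot(obj.track_x - point[0], obj.track_y - point[1])
    return float(d.min()) if d.size else math.inf


def _inside_box(p: np.ndarray) -> bool:
    x_lo, x_hi, y_lo, y_hi = _GAZE_BOX
    return x_lo <= p[0] <= x_hi and y_lo <= p[1] <= y_hi


def _choose_target(
    cur: np.ndarray,
    amplitude: float,
    rng: np.random.Generator,
    avoid: TargetObject | None,
    homing: bool,
) -> np.ndarray:
    """A saccade target at the requested amplitude, inside the gaze box and
    away from any pending object's track; falls back to aiming at the scene
    centre when the constraints cannot be met at that amplitude."""
    if homing:
        centre = np.array([rng.uniform(-4.0, 4.0), rng.uniform(-4.0, 2.0)])
        d = centre - cur
        dist = float(np.hypot(*d))
        if dist > 1e-6:
            return cur + d * min(1.0, amplitude / dist)
    for _ in range(40):
        ang = rng.uniform(0.0, 2.0 * math.pi)
        cand = cur + amplitude * np.array([math.cos(ang), math.sin(ang)])
        if not _inside_box(cand):
            continue
        if avoid is not None and _track_min_distance(cand, avoid) < _AVOID_DEG:
            continue
        return cand
    centre = np.array([0.0, -2.0])
    d = centre - cur
    dist = float(np.hypot(*d))
    step = min(amplitude, max(dist, 1.6))
    return cur + d / max(dist, 1e-9) * step


def generate_subject(
    cfg: GeneratorConfig,
    subject: SubjectAttributes | None = None,
) -> tuple[GazeTrace, ScenarioLog, GroundTruth]:
    """Simulate one drive: trace, scenario log with responses, ground truth.

    Fully reproducible from ``cfg.seed``; the same configuration always
    yields identical arrays and files.
    """
    rng = np.random.default_rng(cfg.seed)
    scenario = generate_scenario(cfg, rng)
    subject = subject or SubjectAttributes()
    dt = cfg.dt
    n = int(round(cfg.duration_s / dt)) + 1
    t = np.arange(n) * dt

    # ---- script object latencies and manual responses -------------------
    course_code = 1 if cfg.course == "ancient" else 0
    scripted = []
    obj_rows = []
    for obj in sorted(scenario.objects, key=lambda o: o.onset):
        ecc = 1 if obj.eccentricity == "far" else 0
        lat = (
            cfg.fix_latency_base_ms
            + cfg.fix_latency_ecc_ms * ecc
            + cfg.fix_latency_course_ms * course_code
            + cfg.fix_latency_ecc_course_ms * ecc * course_code
            + subject.rt_shift_ms
            + float(np.clip(rng.normal(0.0, cfg.rt_noise_sd_ms), -3.5 * cfg.rt_noise_sd_ms, 3.5 * cfg.rt_noise_sd_ms))
        )
        lat = float(np.clip(lat, 350.0, _max_latency_s(cfg) * 1000.0))
        t_arr = round((obj.onset + lat / 1000.0) / dt) * dt
        fix_lat = (t_arr - obj.onset) * 1000.0
        manual_first = rng.random() < cfg.manual_first_prob
        if manual_first:
            manual_lat = max(200.0, fix_lat - cfg.manual_first_advance_ms)
        else:
            manual_lat = fix_lat + cfg.motor_delay_ms
        channel = "brake" if rng.random() < 0.7 else "indicator"
        scenario.responses.append(ManualResponse(t=obj.onset + manual_lat / 1000.0, channel=channel))
        landing = np.array(obj.position_at(t_arr))
        scripted.append({"obj": obj, "t_arr": t_arr, "landing": landing})
        obj_rows.append(
            {
                "object_id": obj.id,
                "kind": obj.kind,
                "eccentricity": obj.eccentricity,
                "course": cfg.course,
                "onset": obj.onset,
                "fix_latency_ms": fix_lat,
                "manual_latency_ms": manual_lat,
                "first_mode": "manual_first" if manual_first else "fixation_first",
                "landing_x": landing[0],
                "landing_y": landing[1],
            }
        )
    scenario.responses.sort(key=lambda r: r.t)

    # ---- plan and synthesize the trace -----------------------------------
    gaze = _ChannelWriter(t, 0.0, 0.0)
    head = _ChannelWriter(t, 0.0, 0.0)
    tr_sacc, tr_head, tr_vor, tr_blink = [], [], [], []

    cycle = cfg.fix_dur_mean_s + 0.15
    p_blink = cfg.blink_rate_per_min / 60.0 * cycle
    p_vor = cfg.vor_rate_per_min / 60.0 * cycle
    k_sacc = 0
    curved_count = 0
    cur_time = 0.4
    si = 0
    homing = False

    def next_curved() -> bool:
        """Deterministic thinning: every saccade (background or scripted) may
        be curved, at exactly the configured fraction of the sequence."""
        nonlocal k_sacc
        f = cfg.curved_fraction
        out = (
            f > 0.0
            and math.floor((k_sacc + 1) * f + 0.5) > math.floor(k_sacc * f + 0.5)
        )
        k_sacc += 1
        return out

    def place_saccade(
        t_start: float,
        target: np.ndarray,
        curved: bool,
        side: int,
        scripted_flag: bool,
        arc_excess: float | None = None,
    ) -> float:
        """Write one gaze saccade (plus head contribution); returns end time."""
        nonlocal curved_count
        p0 = gaze.cur.copy()
        delta = np.asarray(target) - p0
        chord = float(np.hypot(*delta))
        if curved:
            arc_len = chord + (arc_excess if arc_excess is not None else 16.0 + rng.uniform(0.0, 5.0))
            dur, vpk = _saccade_duration(cfg, arc_len)
            gaze.arc(t_start, dur, target, arc_len, side)
            curved_count += 1
        else:
            arc_len = chord
            dur, vpk = _saccade_duration(cfg, chord)
            gaze.line(t_start, dur, target)
        end = t_start + dur
        tr_sacc.append(
            {
                "onset": t_start,
                "offset": end,
                "amplitude": chord,
                "arc_length": arc_len,
                "peak_velocity": vpk,
                "duration": dur,
                "curved": curved,
                "scripted": scripted_flag,
            }
        )
        if not curved and chord > cfg.head_contribution_threshold:
            amp_h = max(chord - cfg.head_contribution_threshold, cfg.head_min_amplitude)
            vec_h = delta / chord * amp_h
            dur_h, vpk_h = _head_duration(amp_h)
            h_start = t_start + cfg.head_lag_s
            head.line(h_start, dur_h, head.cur + vec_h)
            tr_head.append(
                {
                    "onset": h_start,
                    "offset": h_start + dur_h,
                    "amplitude": amp_h,
                    "peak_velocity": vpk_h,
                }
            )
            end = max(end, h_start + dur_h)
        return end

    while cur_time < cfg.duration_s - 1.5:
        nxt = scripted[si] if si < len(scripted) else None
        if nxt is not None:
            budget = (nxt["t_arr"] - _SCRIPT_GUARD_S) - cur_time
            if budget < cfg.fix_dur_min_s + _SETTLE_S:
                # hold the current fixation, then saccade onto the object
                target = nxt["landing"]
                chord = float(np.hypot(*(target - gaze.cur)))
                if chord < cfg.amp_min:
                    # parked too close to the upcoming object: hop away first
                    away = gaze.cur + 4.0 * (gaze.cur - target) / max(chord, 1e-9)
                    hop_start = round((cur_time + cfg.fix_dur_min_s) / dt) * dt
                    cur_time = place_saccade(hop_start, away, curved=False, side=1, scripted_flag=False)
                    continue
                curved = next_curved()
                dur, _ = _saccade_duration(cfg, chord + 16.0 if curved else chord)
                t_start = nxt["t_arr"] - dur
                side = 1 if rng.random() < 0.5 else -1
                end = place_saccade(
                    t_start, target, curved=curved, side=side, scripted_flag=True,
                    arc_excess=16.0 if curved else None,
                )
                cur_time = max(end, nxt["t_arr"] + cfg.object_hold_s)
                si += 1
                homing = True
                continue
        # background action after a fixation
        d = float(np.clip(rng.gamma(4.0, cfg.fix_dur_mean_s / 4.0), cfg.fix_dur_min_s, cfg.fix_dur_max_s))
        if nxt is not None:
            d = min(d, budget - 0.9)
        start = round((cur_time + d) / dt) * dt
        if start > cfg.duration_s - 1.2:
            break
        u = rng.random()
        if u < p_blink:
            # two fast vertical excursions (down, pause, up)
            y_base = gaze.cur[1]
            down = gaze.cur + np.array([0.0, -_BLINK_AMPLITUDE])
            gaze.line(start, _BLINK_MOVE_S, down)
            up_start = start + _BLINK_MOVE_S + _BLINK_PAUSE_S
            gaze.line(up_start, _BLINK_MOVE_S, down + np.array([0.0, _BLINK_AMPLITUDE]))
            vpk = 1.875 * _BLINK_AMPLITUDE / _BLINK_MOVE_S
            tr_blink.append({"onset": start, "offset": start + _BLINK_MOVE_S, "peak_velocity": vpk})
            tr_blink.append({"onset": up_start, "offset": up_start + _BLINK_MOVE_S, "peak_velocity": vpk})
            cur_time = up_start + _BLINK_MOVE_S
            del y_base
        elif u < p_blink + p_vor:
            # head turn fully compensated by the eye: out, pause, back
            amp = rng.uniform(4.0, 8.0)
            direction = 1.0 if rng.random() < 0.5 else -1.0
            dur_h, vpk_h = _head_duration(amp)
            out = head.cur + np.array([direction * amp, 0.0])
            head.line(start, dur_h, out)
            back_start = start + dur_h + _VOR_PAUSE_S
            head.line(back_start, dur_h, out - np.array([direction * amp, 0.0]))
            for t0_, d0_ in ((start, direction), (back_start, -direction)):
                tr_vor.append(
                    {
                        "onset": t0_,
                        "offset": t0_ + dur_h,
                        "amplitude": amp,
                        "head_direction": d0_,
                        "peak_velocity": vpk_h,
                    }
                )
            cur_time = back_start + dur_h
        else:
            curved = next_curved()
            if curved:
                amp = rng.uniform(2.5, 8.0)
            else:
                amp = float(
                    min(cfg.amp_min + rng.gamma(cfg.amp_gamma_shape, cfg.amp_gamma_scale), cfg.amp_max)
                )
            target = _choose_target(gaze.cur, amp, rng, nxt["obj"] if nxt else None, homing)
            homing = False
            side = 1 if rng.random() < 0.5 else -1
            if float(np.hypot(*(target - gaze.cur))) <= cfg.amp_min:
                cur_time = start + 0.05
                continue
            cur_time = place_saccade(start, target, curved=curved, side=side, scripted_flag=False)

    gaze.finish()
    head.finish()

    eye_x = gaze.x - head.x
    eye_y = gaze.y - head.y
    head_x = head.x
    head_y = head.y
    if cfg.position_noise_sd > 0:
        eye_x = eye_x + rng.normal(0.0, cfg.position_noise_sd, n)
        eye_y = eye_y + rng.normal(0.0, cfg.position_noise_sd, n)
    if cfg.head_noise_sd > 0:
        head_x = head_x + rng.normal(0.0, cfg.head_noise_sd, n)
        head_y = head_y + rng.normal(0.0, cfg.head_noise_sd, n)

    trace = GazeTrace(t=t, eye_x=eye_x, eye_y=eye_y, head_x=head_x, head_y=head_y)
    truth = GroundTruth(
        saccades=pd.DataFrame(tr_sacc),
        head_movements=pd.DataFrame(tr_head),
        vor=pd.DataFrame(tr_vor),
        blinks=pd.DataFrame(tr_blink),
        objects=pd.DataFrame(obj_rows),
        subject=subject,
    )
    return trace, scenario, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _draw_subject(rng: np.random.Generator, subject_id: str, rt_sd: float) -> SubjectAttributes:
    age = rng.uniform(20.0, 75.0)
    p_ext = 0.45 / (1.0 + math.exp((age - 33.0) / 5.0))
    p_mod = 0.40 / (1.0 + math.exp((age - 48.0) / 8.0))
    u = rng.random()
    vg = "extensive" if u < p_ext else ("moderate" if u < p_ext + p_mod else "minimum")
    gender = "female" if rng.random() < 0.5 else "male"
    driving = float(np.clip(age - 18.0 - rng.exponential(4.0), 0.0, None))
    malaise = "yes" if rng.random() < 0.3 else "no"
    shift = float(np.clip(rng.normal(0.0, rt_sd), -3.0 * rt_sd, 3.0 * rt_sd)) if rt_sd > 0 else 0.0
    return SubjectAttributes(
        subject_id=subject_id,
        age=age,
        vg_group=vg,
        gender=gender,
        driving_experience=driving,
        malaise=malaise,
        rt_shift_ms=shift,
    )


def generate_cohort(
    n_subjects: int,
    cfg: GeneratorConfig,
    out_dir=None,
):
    """Simulate a cohort of drives with per-subject covariates.

    Returns ``(subjects, results)``: a table of subject attributes and, when
    ``out_dir`` is None, the in-memory ``(trace, scenario, truth)`` triples;
    otherwise the trace/scenario files are written under ``out_dir`` and the
    per-subject path prefixes returned instead.
    """
    if n_subjects < 2:
        raise InsufficientDataError("a cohort needs at least 2 subjects")
    attr_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 77]))
    child_seeds = np.random.SeedSequence(cfg.seed).spawn(n_subjects)
    rows = []
    results = []
    for i in range(n_subjects):
        sid = f"s{i + 1:03d}"
        subj = _draw_subject(attr_rng, sid, cfg.subject_rt_sd_ms)
        seed_i = int(child_seeds[i].generate_state(1)[0] % (2**31))
        cfg_i = dataclasses.replace(cfg, seed=seed_i)
        trace, scenario, truth = generate_subject(cfg_i, subject=subj)
        rows.append(
            {
                "subject": sid,
                "age": subj.age,
                "vg_group": subj.vg_group,
                "gender": subj.gender,
                "driving_experience": subj.driving_experience,
                "malaise": subj.malaise,
                "rt_shift_ms": subj.rt_shift_ms,
                "seed": seed_i,
            }
        )
        if out_dir is None:
            results.append((trace, scenario, truth))
        else:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            prefix = out / f"{sid}_{cfg.course}"
            save_trace(trace, f"{prefix}_trace.csv")
            save_scenario(scenario, prefix)
            truth.objects.to_csv(f"{prefix}_truth.tsv", sep="\t", index=False)
            results.append(str(prefix))
    return pd.DataFrame(rows), results


#: Fixed-effect magnitudes (ms) used as simulation truth for the median
#: manual reaction-time cohort model, together with subject SD 311.22 and
#: residual SD 448.70.
MANUAL_RT_EFFECTS = {
    "intercept": 1168.8442,
    "age_c": 2.1077,
    "eccentricity": 1300.1934,
    "course": -96.3001,
    "age_c:eccentricity": 1.7190,
    "age_c:course": 0.2802,
    "eccentricity:course": 956.0274,
    "vg_moderate": -82.3265,
    "vg_extensive": 50.1128,
    "eccentricity:vg_extensive": -509.1063,
    "course:vg_extensive": 196.0442,
    "eccentricity:vg_moderate": -269.9960,
    "course:vg_moderate": 71.6985,
    "age_c:vg_extensive": 7.1096,
    "age_c:vg_moderate": 6.3935,
}

MANUAL_RT_SUBJECT_SD = 311.22
MANUAL_RT_RESIDUAL_SD = 448.70


def generate_cohort_table(
    n_subjects: int = 73,
    effects: dict | None = None,
    subject_sd: float = MANUAL_RT_SUBJECT_SD,
    residual_sd: float = MANUAL_RT_RESIDUAL_SD,
    seed: int = 0,
    response: str = "median_rt_manual",
) -> pd.DataFrame:
    """Simulate the subject x eccentricity x course response table directly.

    The linear predictor is formed from the coded design (including two-way
    interactions) with the given fixed-effect magnitudes, plus a
    subject-level random intercept and i.i.d. residual noise.  Ages are
    uniform on [20, 75]; game-experience group probabilities decrease with
    age.  Returns the raw (label-coded) long table ready for
    :func:`drivegaze.design.code_design`.
    """
    from .design import code_design  # local import to avoid a cycle

    if n_subjects < 2:
        raise InsufficientDataError("a cohort needs at least 2 subjects")
    effects = MANUAL_RT_EFFECTS if effects is None else effects
    rng = np.random.default_rng(seed)
    subs = [_draw_subject(rng, f"s{i + 1:03d}", 0.0) for i in range(n_subjects)]
    rows = []
    for s in subs:
        for course in ("field", "ancient"):
            for ecc in ("close", "far"):
                rows.append(
                    {
                        "subject": s.subject_id,
                        "age": s.age,
                        "vg_group": s.vg_group,
                        "gender": s.gender,
                        "driving_experience": s.driving_experience,
                        "malaise": s.malaise,
                        "eccentricity": ecc,
                        "course": course,
                        response: 0.0,
                    }
                )
    raw = pd.DataFrame(rows)
    design = code_design(raw, response)
    X = design.exog()
    unknown = set(effects) - set(X.columns)
    if unknown:
        raise ConfigError(f"unknown effect term(s): {sorted(unknown)}")
    beta = np.array([effects.get(c, 0.0) for c in X.columns])
    u = dict(zip([s.subject_id for s in subs], rng.normal(0.0, subject_sd, n_subjects)))
    eps = rng.normal(0.0, residual_sd, len(raw))
    raw[response] = X.to_numpy() @ beta + raw["subject"].map(u).to_numpy() + eps
    return raw


# ---------------------------------------------------------------------------
# ground-truth comparison
# ---------------------------------------------------------------------------

def evaluate_detection(truth: pd.DataFrame, detected, amplitude: bool = True) -> dict:
    """Greedy interval-overlap matching of detected events to ground truth.

    Returns counts, precision, recall, and the per-pair onset and amplitude
    errors.
    """
    det = sorted(detected, key=lambda e: e.onset)
    used = [False] * len(det)
    onset_err, amp_err, pairs = [], [], 0
    rows = truth.sort_values("onset") if len(truth) else truth
    for row in rows.itertuples(index=False):
        for k, ev in enumerate(det):
            if used[k]:
                continue
            if ev.onset > row.offset:
                break
            if ev.offset >= row.onset:
                used[k] = True
                pairs += 1
                onset_err.append(abs(ev.onset - row.onset))
                if amplitude and hasattr(row, "amplitude"):
                    amp_err.append(abs(ev.amplitude - row.amplitude))
                break
    n_truth = len(truth)
    n_det = len(det)
    return {
        "n_truth": n_truth,
        "n_detected": n_det,
        "n_matched": pairs,
        "recall": pairs / n_truth if n_truth else math.nan,
        "precision": pairs / n_det if n_det else math.nan,
        "max_onset_error": max(onset_err) if onset_err else math.nan,
        "max_amplitude_error": max(amp_err) if amp_err else math.nan,
    }
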