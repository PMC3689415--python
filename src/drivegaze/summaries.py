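"""Per-subject oculomotor summary metrics.

One row per subject x course: mean fixation duration, mean saccade
amplitude, saccade count, the spread of search as the variance of fixation
centroid locations in pixel coordinates (horizontal and vertical), the
VOR-excluded head-movement count, and median reaction times per target
eccentricity for both reaction modes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .events import Fixation, HeadMovement, Saccade
from .geometry import ScreenGeometry
from .reactions import ReactionRecord

__all__ = ["subject_summary", "summaries_table"]


def _median_or_nan(values) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return float(np.median(vals)) if vals else math.nan


def subject_summary(
    subject_id,
    course: str,
    saccades: list[Saccade],
    fixations: list[Fixation],
    head_movements: list[HeadMovement],
    records: list[ReactionRecord],
    geom: ScreenGeometry | None = None,
) -> dict:
    """Summary metrics for one subject and course.

    ``head_movements`` must already be VOR-filtered.  Fixation-location
    variance uses sample (n-1) variance of the centroid pixel coordinates
    and is missing (NaN), not zero, when fewer than two fixations exist.
    Median reaction times are taken over detected objects only.
    """
    geom = geom or ScreenGeometry()
    if fixations:
        px = np.array([f.centroid_px[0] if f.centroid_px else geom.deg_to_px(f.centroid_x, f.centroid_y)[0] for f in fixations])
        py = np.array([f.centroid_px[1] if f.centroid_px else geom.deg_to_px(f.centroid_x, f.centroid_y)[1] for f in fixations])
        var_x = float(np.var(px, ddof=1)) if px.size >= 2 else math.nan
        var_y = float(np.var(py, ddof=1)) if py.size >= 2 else math.nan
        mean_fix = float(np.mean([f.duration for f in fixations])) * 1000.0
    else:
        var_x = var_y = mean_fix = math.nan
    detected = [r for r in records if r.detected]
    out = {
        "subject": subject_id,
        "course": course,
        "mean_fixation_duration_ms": mean_fix,
        "mean_saccade_amplitude_deg": float(np.mean([s.amplitude for s in saccades])) if saccades else math.nan,
        "n_saccades": len(saccades),
        "var_fixation_x_px2": var_x,
        "var_fixation_y_px2": var_y,
        "n_head_movements": len(head_movements),
    }
    for ecc in ("close", "far"):
        sub = [r for r in detected if r.eccentricity == ecc]
        out[f"median_rt_manual_{ecc}_ms"] = _median_or_nan([r.rt_manual_ms for r in sub])
        out[f"median_rt_first_{ecc}_ms"] = _median_or_nan([r.rt_first_detection_ms for r in sub])
    return out


def summaries_table(rows: list[dict]) -> pd.DataFrame:
    """Stack per-subject summary dicts into a DataFrame."""
    return pd.DataFrame(rows)
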