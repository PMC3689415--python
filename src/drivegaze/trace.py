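"""The synchronized eye / head / gaze time-series container.

A :class:`GazeTrace` holds eye-in-head and head orientation per axis in
degrees, sampled nominally at 100 Hz.  Gaze (eye-in-space) is always the
derived sum of the two channels, so the invariant ``gaze = eye + head`` holds
by construction.  Samples lost by the tracker are retained and flagged
invalid rather than dropped, so that event detection can treat tracking-loss
episodes explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError

__all__ = ["GazeTrace"]

TRACE_COLUMNS = ("t", "eye_x", "eye_y", "head_x", "head_y", "valid")


@dataclass
class GazeTrace:
    """Eye-in-head and head orientation time series.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing.
    eye_x, eye_y : ndarray
        Eye-in-head orientation in degrees.
    head_x, head_y : ndarray
        Head orientation in degrees.
    valid : ndarray of bool, optional
        Per-sample validity flag; defaults to all valid.
    """

    t: np.ndarray
    eye_x: np.ndarray
    eye_y: np.ndarray
    head_x: np.ndarray
    head_y: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("eye_x", "eye_y", "head_x", "head_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise FormatError(f"column {name!r} has length {arr.size}, expected {self.t.size}")
            setattr(self, name, arr)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid).astype(bool)
            if self.valid.shape != self.t.shape:
                raise FormatError("column 'valid' has wrong length")
        bad = np.flatnonzero(np.diff(self.t) <= 0)
        if bad.size:
            raise FormatError(f"time not strictly increasing at row {bad[0] + 1}")

    # -- derived channels --------------------------------------------------

    @property
    def gaze_x(self) -> np.ndarray:
        return self.eye_x + self.head_x

    @property
    def gaze_y(self) -> np.ndarray:
        return self.eye_y + self.head_y

    @property
    def n(self) -> int:
        return int(self.t.size)

    @property
    def dt(self) -> float:
        """Nominal sampling interval (median inter-sample interval)."""
        return float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    # -- conversions -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with derived gaze columns included."""
        return pd.DataFrame(
            {
                "t": self.t,
                "eye_x": self.eye_x,
                "eye_y": self.eye_y,
                "head_x": self.head_x,
                "head_y": self.head_y,
                "gaze_x": self.gaze_x,
                "gaze_y": self.gaze_y,
                "valid": self.valid.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GazeTrace":
        missing = [c for c in TRACE_COLUMNS if c not in frame.columns and c != "valid"]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        valid = frame["valid"].to_numpy() if "valid" in frame.columns else None
        return cls(
            t=frame["t"].to_numpy(dtype=float),
            eye_x=frame["eye_x"].to_numpy(dtype=float),
            eye_y=frame["eye_y"].to_numpy(dtype=float),
            head_x=frame["head_x"].to_numpy(dtype=float),
            head_y=frame["head_y"].to_numpy(dtype=float),
            valid=valid,
        )
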