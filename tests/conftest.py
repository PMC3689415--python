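"""Shared fixtures and a hand-rolled trace builder.

The builder composes minimum-jerk position steps directly with numpy, so
tests that use it as ground truth stay independent of the package's own
synthetic-data generator.
"""

import numpy as np
import pytest

from drivegaze import DetectionConfig, GazeTrace, ScreenGeometry


@pytest.fixture
def geom() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture
def cfg() -> DetectionConfig:
    return DetectionConfig()


def minjerk_profile(t, t0, dur):
    tau = np.clip((t - t0) / dur, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau * tau)


def make_trace(
    eye_steps=(),
    head_steps=(),
    duration=4.0,
    dt=0.01,
    noise_sd=0.0,
    seed=0,
    start=(0.0, 0.0),
):
    """Build a trace from (t_start, dur, dx, dy) min-jerk steps per channel."""
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    eye = np.zeros((n, 2))
    head = np.zeros((n, 2))
    eye[:, 0] += start[0]
    eye[:, 1] += start[1]
    for t0, dur, dx, dy in eye_steps:
        s = minjerk_profile(t, t0, dur)
        eye[:, 0] += dx * s
        eye[:, 1] += dy * s
    for t0, dur, dx, dy in head_steps:
        s = minjerk_profile(t, t0, dur)
        head[:, 0] += dx * s
        head[:, 1] += dy * s
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eye += rng.normal(0.0, noise_sd, eye.shape)
    return GazeTrace(
        t=t,
        eye_x=eye[:, 0],
        eye_y=eye[:, 1],
        head_x=head[:, 0],
        head_y=head[:, 1],
    )
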