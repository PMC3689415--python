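import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivegaze import (
    DetectionConfig,
    GazeTrace,
    InsufficientDataError,
    ScreenGeometry,
    classify_saccade,
    compute_velocity,
    detect_events,
    detect_head_movements,
    detect_saccades,
    detect_vor,
    filter_head_movements,
    main_sequence,
    segment_fixations,
)
from drivegaze.events import Saccade, classify_saccades

from conftest import make_trace


class TestVelocity:
    def test_constant_position_zero_velocity(self):
        tr = make_trace(duration=1.0)
        v = compute_velocity(tr)
        assert np.nanmax(v.speed) == 0.0

    def test_linear_ramp_exact(self):
        n = 101
        t = np.arange(n) * 0.01
        tr = GazeTrace(t=t, eye_x=10.0 * t, eye_y=np.zeros(n), head_x=np.zeros(n), head_y=np.zeros(n))
        v = compute_velocity(tr)
        # central differences are exact on linear signals at interior samples
        assert np.allclose(v.speed[1:-1], 10.0, atol=1e-9)
        assert np.isnan(v.speed[0]) and np.isnan(v.speed[-1])

    def test_minjerk_peak_matches_direct_differencing(self):
        tr = make_trace(eye_steps=[(0.5, 0.05, 10.0, 0.0)], duration=1.2)
        v = compute_velocity(tr)
        # independent oracle: brute-force per-sample central differencing
        x = tr.gaze_x
        expected = np.abs((x[2:] - x[:-2]) / 0.02).max()
        assert np.nanmax(v.speed) == pytest.approx(expected, rel=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            compute_velocity(make_trace(duration=0.01))

    def test_invalid_samples_undefined(self):
        tr = make_trace(duration=0.5)
        tr.valid[20] = False
        v = compute_velocity(tr)
        assert np.isnan(v.speed[19:22]).all()
        assert not np.isnan(v.speed[23])


class TestSaccadeDetection:
    def test_single_step(self, cfg):
        tr = make_trace(eye_steps=[(1.0, 0.06, 10.0, 0.0)], duration=3.0)
        sacc = detect_saccades(tr, cfg)
        assert len(sacc) == 1
        assert sacc[0].amplitude == pytest.approx(10.0, abs=0.1)
        assert abs(sacc[0].onset - 1.0) <= 0.01 + 1e-9
        assert sacc[0].peak_velocity > cfg.saccade_vel_thresh
        assert sacc[0].arc_length >= sacc[0].amplitude - 1e-9

    def test_stationary_no_saccades(self, cfg):
        assert detect_saccades(make_trace(duration=2.0), cfg) == []

    def test_two_separated_steps(self, cfg):
        tr = make_trace(eye_steps=[(0.5, 0.05, 5.0, 0.0), (1.05, 0.05, -5.0, 0.0)], duration=2.0)
        assert len(detect_saccades(tr, cfg)) == 2

    def test_sub_amplitude_candidate_discarded(self, cfg):
        # fast enough to cross 30 deg/s, but chord below the 1 deg threshold
        tr = make_trace(eye_steps=[(0.5, 0.04, 0.8, 0.0)], duration=1.5)
        assert detect_saccades(tr, cfg) == []

    def test_thresholds_respected(self, cfg):
        tr = make_trace(
            eye_steps=[(0.5, 0.05, 3.0, 1.0), (1.2, 0.08, -12.0, 2.0), (2.0, 0.1, 20.0, -3.0)],
            duration=3.0,
        )
        for s in detect_saccades(tr, cfg):
            assert s.peak_velocity > cfg.saccade_vel_thresh
            assert s.amplitude > cfg.saccade_amp_thresh


class TestClassification:
    def test_fast_vertical_is_blink(self, cfg):
        tr = make_trace(eye_steps=[(0.5, 0.04, 0.0, -30.0)], duration=1.5)
        sacc = detect_saccades(tr, cfg)
        assert len(sacc) == 1
        retained, blinks = classify_saccades(sacc, tr, cfg)
        assert retained == [] and len(blinks) == 1
        assert blinks[0].peak_velocity > cfg.blink_peak_vel_thresh

    def test_fast_horizontal_is_not_blink(self, cfg):
        tr = make_trace(eye_steps=[(0.5, 0.05, 25.0, 0.0)], duration=1.5)
        sacc = detect_saccades(tr, cfg)
        retained, blinks = classify_saccades(sacc, tr, cfg)
        assert len(retained) == 1 and blinks == []

    @pytest.mark.parametrize(
        "chord,arc,expect",
        [(5.0, 21.0, True), (5.0, 5.0, False), (5.0, 19.9, False)],
    )
    def test_curved_rule_is_absolute_excess(self, cfg, chord, arc, expect):
        tr = make_trace(duration=0.2)
        s = Saccade(
            onset=0.0, offset=0.05, i0=0, i1=5, amplitude=chord, arc_length=arc,
            peak_velocity=200.0, duration=0.05, direction=(1.0, 0.0),
        )
        flags = classify_saccade(s, tr, cfg)
        assert flags["curved"] is expect

    def test_offscreen_outside_rectangle(self, cfg, geom):
        tr = make_trace(eye_steps=[(0.5, 0.08, 32.0, 0.0)], duration=1.5)
        sacc = detect_saccades(tr, cfg)
        classify_saccades(sacc, tr, cfg, geom)
        assert sacc[0].offscreen

    def test_offscreen_on_tracking_loss(self, cfg, geom):
        tr = make_trace(eye_steps=[(0.5, 0.06, 10.0, 0.0)], duration=1.5)
        tr.valid[57:60] = False
        sacc = detect_saccades(tr, cfg)
        classify_saccades(sacc, tr, cfg, geom)
        assert len(sacc) >= 1
        assert any(s.offscreen for s in sacc)


class TestFixations:
    def test_no_saccades_single_fixation(self):
        tr = make_trace(duration=2.0)
        fix = segment_fixations(tr, [])
        assert len(fix) == 1
        assert fix[0].duration == pytest.approx(tr.duration)

    def test_one_saccade_two_fixations(self, cfg):
        tr = make_trace(eye_steps=[(1.0, 0.06, 10.0, 0.0)], duration=2.0)
        sacc = detect_saccades(tr, cfg)
        fix = segment_fixations(tr, sacc)
        assert len(fix) == 2
        assert fix[0].centroid_x == pytest.approx(0.0, abs=0.05)
        assert fix[1].centroid_x == pytest.approx(10.0, abs=0.05)

    def test_partition_tiles_trace(self, cfg):
        tr = make_trace(
            eye_steps=[(0.5, 0.05, 6.0, 0.0), (1.2, 0.07, -8.0, 3.0), (2.3, 0.06, 5.0, -2.0)],
            duration=3.0,
        )
        sacc = detect_saccades(tr, cfg)
        fix = segment_fixations(tr, sacc)
        total = sum(f.duration for f in fix) + sum(s.duration for s in sacc)
        assert total == pytest.approx(tr.duration, abs=tr.dt)

    def test_partition_with_invalid_span(self, cfg):
        tr = make_trace(eye_steps=[(0.5, 0.06, 6.0, 0.0)], duration=2.0)
        tr.valid[120:140] = False
        sacc = detect_saccades(tr, cfg)
        fix = segment_fixations(tr, sacc)
        valid_time = (120 - 1) * tr.dt + (tr.n - 140 - 1) * tr.dt
        total = sum(f.duration for f in fix) + sum(s.duration for s in sacc)
        assert total == pytest.approx(valid_time, abs=2 * tr.dt)


class TestHeadMovements:
    def test_still_head_none(self, cfg):
        assert detect_head_movements(make_trace(duration=1.0), cfg) == []

    def test_head_turn_detected(self, cfg):
        tr = make_trace(head_steps=[(0.5, 0.3, 10.0, 0.0)], duration=2.0)
        hm = detect_head_movements(tr, cfg)
        assert len(hm) == 1
        assert hm[0].amplitude == pytest.approx(10.0, abs=0.1)

    def test_small_drift_below_amplitude_threshold(self, cfg):
        # fast enough (about 19 deg/s) but only 2 deg amplitude
        tr = make_trace(head_steps=[(0.5, 0.2, 2.0, 0.0)], duration=1.5)
        assert detect_head_movements(tr, cfg) == []


class TestVOR:
    def test_counter_phase_excluded(self, cfg):
        tr = make_trace(
            eye_steps=[(0.5, 0.3, 10.0, 0.0)],
            head_steps=[(0.5, 0.3, -10.0, 0.0)],
            duration=1.5,
        )
        hm = detect_head_movements(tr, cfg)
        assert len(hm) == 1
        vor = detect_vor(tr, hm, cfg)
        assert len(vor) == 1
        assert vor[0].eye_direction * vor[0].head_direction == -1
        assert filter_head_movements(hm, vor) == []
        # the cancelled movement adds no gaze amplitude
        assert abs(tr.gaze_x[-1] - tr.gaze_x[0]) < 0.2

    def test_same_direction_counted(self, cfg):
        tr = make_trace(
            eye_steps=[(0.5, 0.3, 5.0, 0.0)],
            head_steps=[(0.5, 0.3, 5.0, 0.0)],
            duration=1.5,
        )
        hm = detect_head_movements(tr, cfg)
        vor = detect_vor(tr, hm, cfg)
        assert vor == []
        assert len(filter_head_movements(hm, vor)) == 1

    def test_head_alone_counted(self, cfg):
        tr = make_trace(head_steps=[(0.5, 0.3, 8.0, 0.0)], duration=1.5)
        hm = detect_head_movements(tr, cfg)
        vor = detect_vor(tr, hm, cfg)
        assert vor == []
        assert len(filter_head_movements(hm, vor)) == 1

    def test_filtering_never_increases_count(self, cfg):
        tr = make_trace(
            eye_steps=[(0.5, 0.3, -6.0, 0.0)],
            head_steps=[(0.5, 0.3, 6.0, 0.0), (1.2, 0.3, 7.0, 0.0)],
            duration=2.0,
        )
        hm = detect_head_movements(tr, cfg)
        assert len(filter_head_movements(hm, detect_vor(tr, hm, cfg))) <= len(hm)


class TestMainSequence:
    @staticmethod
    def _mk(amp, curved=False):
        return Saccade(
            onset=0.0, offset=0.05, i0=0, i1=5, amplitude=amp, arc_length=amp + (16 if curved else 0),
            peak_velocity=500 * (1 - np.exp(-amp / 14)), duration=0.05, direction=(1, 0), curved=curved,
        )

    def test_single_saccade_row(self):
        res = main_sequence([self._mk(8.0)])
        assert len(res.table) == 1
        assert res.table.iloc[0]["amplitude"] == 8.0
        assert res.curved_fraction == 0.0

    def test_curved_fraction_counting(self):
        sacc = [self._mk(5.0) for _ in range(97)] + [self._mk(5.0, curved=True) for _ in range(3)]
        assert main_sequence(sacc).curved_fraction == pytest.approx(0.03)

    def test_empty_input(self):
        res = main_sequence([])
        assert len(res.table) == 0
        assert np.isnan(res.curved_fraction)


class TestOracleEquivalence:
    """Detection must reproduce hand-constructed step trains exactly."""

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_step_trains_recovered(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(0, 6))
        steps = []
        t0 = 0.5
        for _ in range(k):
            amp = float(rng.uniform(1.5, 18.0))
            ang = float(rng.uniform(0, 2 * np.pi))
            dur = float(rng.uniform(0.04, 0.09))
            steps.append((t0, dur, amp * np.cos(ang), amp * np.sin(ang)))
            t0 += dur + float(rng.uniform(0.3, 0.6))
        tr = make_trace(eye_steps=steps, duration=t0 + 0.5)
        cfg = DetectionConfig()
        sacc = detect_saccades(tr, cfg)
        assert len(sacc) == k
        for s, (ts, dur, dx, dy) in zip(sacc, steps):
            assert abs(s.onset - ts) <= tr.dt + 1e-9
            assert s.amplitude == pytest.approx(np.hypot(dx, dy), abs=0.1)
        fix = segment_fixations(tr, sacc)
        assert len(fix) == k + 1
        total = sum(f.duration for f in fix) + sum(s.duration for s in sacc)
        assert total == pytest.approx(tr.duration, abs=tr.dt)


class TestTimeOriginInvariance:
    def test_shifted_trace_same_events(self, cfg):
        tr = make_trace(eye_steps=[(0.5, 0.05, 6.0, 0.0), (1.4, 0.07, -9.0, 2.0)], duration=2.5)
        shifted = GazeTrace(
            t=tr.t + 1000.0, eye_x=tr.eye_x, eye_y=tr.eye_y, head_x=tr.head_x, head_y=tr.head_y
        )
        a = detect_events(tr, cfg)
        b = detect_events(shifted, cfg)
        assert len(a.saccades) == len(b.saccades)
        for sa, sb in zip(a.saccades, b.saccades):
            assert sb.onset - sa.onset == pytest.approx(1000.0, abs=1e-6)
            assert sb.amplitude == pytest.approx(sa.amplitude, abs=1e-9)
        assert [f.duration for f in a.fixations] == pytest.approx(
            [f.duration for f in b.fixations], abs=1e-9
        )
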