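import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from drivegaze import (
    ConfigError,
    DetectionConfig,
    GeneratorConfig,
    InsufficientDataError,
    detect_events,
    evaluate_detection,
    generate_cohort,
    generate_cohort_table,
    generate_scenario,
    generate_subject,
    load_scenario,
    load_trace,
    main_sequence,
)

DESK = dict(duration_s=80.0, n_hazard_events=8, n_signs_cars=0)


class TestScenario:
    def test_default_course_has_eight_hazards(self):
        scen = generate_scenario(GeneratorConfig())
        assert scen.n_hazardous == 8

    def test_hazards_cover_kind_side_eccentricity(self):
        scen = generate_scenario(GeneratorConfig(seed=2))
        combos = {(o.kind, o.side, o.eccentricity) for o in scen.objects if o.hazardous}
        assert len(combos) == 8

    def test_onsets_within_course(self):
        cfg = GeneratorConfig(seed=5)
        scen = generate_scenario(cfg)
        for o in scen.objects:
            assert 0 < o.onset < cfg.duration_s

    def test_infeasible_schedule_raises(self):
        with pytest.raises(ConfigError, match="infeasible"):
            generate_scenario(GeneratorConfig(duration_s=20.0, n_hazard_events=8))


class TestGenerateSubject:
    def test_same_seed_identical_output(self):
        cfg = GeneratorConfig(seed=42, duration_s=40.0, n_hazard_events=2, n_signs_cars=1)
        t1, s1, g1 = generate_subject(cfg)
        t2, s2, g2 = generate_subject(cfg)
        assert np.array_equal(t1.eye_x, t2.eye_x)
        assert np.array_equal(t1.head_y, t2.head_y)
        assert [r.t for r in s1.responses] == [r.t for r in s2.responses]
        pd.testing.assert_frame_equal(g1.saccades, g2.saccades)

    def test_truth_obeys_main_sequence_law(self):
        cfg = GeneratorConfig(seed=1, **DESK)
        _, _, truth = generate_subject(cfg)
        straight = truth.saccades.query("~curved")
        law = cfg.v_max * (1 - np.exp(-straight.amplitude / cfg.ms_scale))
        assert np.abs(straight.peak_velocity - law).max() < 1e-6
        # curved saccades follow the law on their arc length instead
        curved = truth.saccades.query("curved")
        if len(curved):
            law_c = cfg.v_max * (1 - np.exp(-curved.arc_length / cfg.ms_scale))
            assert np.abs(curved.peak_velocity - law_c).max() < 1e-6

    def test_noise_free_detection_recovers_truth_exactly(self):
        cfg = GeneratorConfig(
            seed=7, position_noise_sd=0.0, head_noise_sd=0.0, **DESK
        )
        trace, _, truth = generate_subject(cfg)
        ev = detect_events(trace, DetectionConfig())
        assert len(ev.saccades) == len(truth.saccades)
        assert len(ev.blinks) == len(truth.blinks)
        assert len(ev.head_movements_filtered) == len(truth.head_movements)

    def test_gaze_is_sum_of_eye_and_head(self):
        trace, _, _ = generate_subject(GeneratorConfig(seed=3, duration_s=40.0, n_hazard_events=2, n_signs_cars=0))
        assert np.allclose(trace.gaze_x, trace.eye_x + trace.head_x)

    def test_rt_first_le_manual_by_construction(self):
        cfg = GeneratorConfig(seed=11, manual_first_prob=0.3, **DESK)
        _, _, truth = generate_subject(cfg)
        first = np.minimum(truth.objects.fix_latency_ms, truth.objects.manual_latency_ms)
        manual_first = truth.objects.first_mode == "manual_first"
        assert (first <= truth.objects.manual_latency_ms + 1e-9).all()
        assert (
            truth.objects.loc[manual_first, "manual_latency_ms"]
            < truth.objects.loc[manual_first, "fix_latency_ms"]
        ).all()

    def test_detected_main_sequence_is_monotone(self):
        cfg = GeneratorConfig(seed=13, **DESK)
        trace, _, _ = generate_subject(cfg)
        ev = detect_events(trace, DetectionConfig())
        res = main_sequence(ev.saccades)
        straight = res.table[~res.table.curved]
        rho = spearmanr(straight.amplitude, straight.peak_velocity).statistic
        assert rho > 0.95

    def test_curved_fraction_close_to_configured(self):
        cfg = GeneratorConfig(seed=17, duration_s=300.0, n_hazard_events=4, n_signs_cars=0)
        _, _, truth = generate_subject(cfg)
        frac = truth.saccades.curved.mean()
        assert frac == pytest.approx(cfg.curved_fraction, abs=0.01)


class TestCohort:
    def test_writes_trace_and_scenario_pairs(self, tmp_path):
        cfg = GeneratorConfig(seed=1, duration_s=40.0, n_hazard_events=2, n_signs_cars=0)
        subjects, prefixes = generate_cohort(3, cfg, out_dir=tmp_path)
        assert len(subjects) == 3 and len(prefixes) == 3
        for p in prefixes:
            tr = load_trace(f"{p}_trace.csv")
            scen = load_scenario(p)
            assert tr.n > 0 and scen.n_hazardous == 2

    def test_too_small_cohort_raises(self):
        with pytest.raises(InsufficientDataError):
            generate_cohort(1, GeneratorConfig())
        with pytest.raises(InsufficientDataError):
            generate_cohort_table(1)

    def test_zero_effect_table_is_pure_noise(self):
        raw = generate_cohort_table(
            30, effects={}, subject_sd=0.0, residual_sd=1.0, seed=3, response="y"
        )
        assert abs(raw["y"].mean()) < 0.2

    def test_injected_eccentricity_effect_visible_in_raw_means(self):
        raw = generate_cohort_table(
            73,
            effects={"intercept": 1000.0, "eccentricity": 1300.0},
            subject_sd=311.0,
            residual_sd=449.0,
            seed=21,
        )
        far = raw.loc[raw.eccentricity == "far", "median_rt_manual"].mean()
        close = raw.loc[raw.eccentricity == "close", "median_rt_manual"].mean()
        se = 449.0 / np.sqrt(len(raw) / 2)
        assert abs((far - close) - 1300.0) < 3 * np.sqrt(2) * se

    def test_ages_uniform_and_experience_age_dependent(self):
        raw = generate_cohort_table(200, effects={}, seed=5)
        subs = raw.drop_duplicates("subject")
        assert subs.age.between(20, 75).all()
        mean_age = subs.groupby("vg_group").age.mean()
        assert mean_age["extensive"] < mean_age["minimum"]
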