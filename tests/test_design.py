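import math

import numpy as np
import pandas as pd
import pytest

from drivegaze import (
    CodingError,
    RankDeficiencyError,
    ScreenGeometry,
    code_design,
    fit_lmm,
    fit_logistic,
    generate_cohort_table,
    subject_summary,
)
from drivegaze.events import Fixation


def _raw_table(rows):
    base = {
        "subject": "s1",
        "age": 40.0,
        "vg_group": "minimum",
        "gender": "male",
        "eccentricity": "close",
        "course": "field",
        "rt": 1000.0,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


class TestCoding:
    def test_baseline_cell_codes_to_zeros(self):
        d = code_design(_raw_table([{}, {"subject": "s2"}]), "rt")
        row = d.data.iloc[0]
        assert (row["eccentricity"], row["course"], row["vg_moderate"], row["vg_extensive"]) == (
            0.0, 0.0, 0.0, 0.0,
        )
        assert row["gender"] == 0.0

    def test_far_ancient_extensive_codes(self):
        d = code_design(
            _raw_table(
                [{"eccentricity": "far", "course": "ancient", "vg_group": "extensive"}, {"subject": "s2"}]
            ),
            "rt",
        )
        row = d.data.iloc[0]
        assert (row["eccentricity"], row["course"], row["vg_moderate"], row["vg_extensive"]) == (
            1.0, 1.0, 0.0, 1.0,
        )

    def test_age_centering_is_exact(self):
        ages = np.linspace(20, 75, 56)
        table = _raw_table([{"subject": f"s{i}", "age": a} for i, a in enumerate(ages)])
        d = code_design(table, "rt")
        assert abs(d.data["age_c"].mean()) < 1e-6

    def test_unknown_label_rejected(self):
        with pytest.raises(CodingError, match="expert"):
            code_design(_raw_table([{"vg_group": "expert"}]), "rt")

    def test_interactions_are_products(self):
        d = code_design(
            _raw_table([{"eccentricity": "far", "course": "ancient"}, {"subject": "s2"}]), "rt"
        )
        row = d.data.iloc[0]
        assert row["eccentricity:course"] == row["eccentricity"] * row["course"]
        assert "vg_moderate:vg_extensive" not in d.data.columns

    def test_coding_is_idempotent(self):
        d1 = code_design(_raw_table([{}, {"subject": "s2", "eccentricity": "far"}]), "rt")
        d2 = code_design(d1.data, "rt")
        pd.testing.assert_frame_equal(d1.data, d2.data)

    def test_dummies_mutually_exclusive(self):
        table = _raw_table(
            [{"vg_group": g, "subject": f"s{i}"} for i, g in enumerate(["minimum", "moderate", "extensive"])]
        )
        d = code_design(table, "rt")
        assert (d.data["vg_moderate"] * d.data["vg_extensive"]).abs().max() == 0.0


class TestMixedModel:
    def test_recovers_injected_effect(self):
        raw = generate_cohort_table(
            40,
            effects={"intercept": 1000.0, "eccentricity": 500.0},
            subject_sd=150.0,
            residual_sd=200.0,
            seed=11,
        )
        d = code_design(raw, "median_rt_manual", fixed_effects=("age_c", "eccentricity", "course"))
        fit = fit_lmm(d)
        e = fit["eccentricity"]
        assert abs(e["estimate"] - 500.0) <= 2 * e["se"]
        assert e["significant"]

    def test_significance_rule_is_t_beyond_two(self):
        raw = generate_cohort_table(
            40, effects={"intercept": 1000.0}, subject_sd=150.0, residual_sd=200.0, seed=4
        )
        fit = fit_lmm(code_design(raw, "median_rt_manual", fixed_effects=("eccentricity", "course")))
        assert list(fit.significant) == [abs(t) > 2.0 for t in fit.stat]

    def test_variance_components_reported(self):
        raw = generate_cohort_table(
            60, effects={"intercept": 1000.0}, subject_sd=300.0, residual_sd=100.0, seed=2
        )
        fit = fit_lmm(code_design(raw, "median_rt_manual", fixed_effects=("eccentricity", "course")))
        assert fit.subject_sd == pytest.approx(300.0, rel=0.4)
        assert fit.residual_sd == pytest.approx(100.0, rel=0.25)

    def test_singular_design_raises_informative(self):
        table = _raw_table(
            [{"subject": f"s{i}", "eccentricity": "close"} for i in range(8)]
        )  # eccentricity constant
        d = code_design(table, "rt", fixed_effects=("eccentricity", "course"))
        with pytest.raises(RankDeficiencyError, match="rank"):
            fit_lmm(d)


class TestLogistic:
    def test_balanced_null_predictor_near_zero(self):
        rows = []
        for i in range(200):
            rows.append(
                {
                    "subject": f"s{i}",
                    "age": 40.0,
                    "gender": "male" if i % 2 else "female",
                    "malaise": "yes" if i % 2 else "no",
                }
            )
        # malaise split identically across gender: no association
        df = pd.DataFrame(rows)
        df["malaise"] = ["yes" if i % 4 < 2 else "no" for i in range(200)]
        d = code_design(df, "malaise", fixed_effects=("gender",), interactions=False)
        fit = fit_logistic(d)
        assert abs(fit["gender"]["estimate"]) < 0.2
        assert not fit["gender"]["significant"]

    def test_recovers_logit_coefficient(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 2, 600)
        p = 1.0 / (1.0 + np.exp(-(-0.5 + 1.2 * x)))
        y = (rng.random(600) < p).astype(float)
        df = pd.DataFrame(
            {"subject": [f"s{i}" for i in range(600)], "gender": x.astype(float), "malaise": y}
        )
        d = code_design(df, "malaise", fixed_effects=("gender",), interactions=False)
        fit = fit_logistic(d)
        g = fit["gender"]
        assert abs(g["estimate"] - 1.2) <= 2 * g["se"]


class TestSubjectSummary:
    @staticmethod
    def _fix_at_px(px, py):
        geom = ScreenGeometry()
        x, y = geom.px_to_deg(px, py)
        return Fixation(
            onset=0.0, offset=0.4, i0=0, i1=1, duration=0.4,
            centroid_x=float(x), centroid_y=float(y), centroid_px=(px, py),
        )

    def test_identical_x_zero_variance(self):
        fix = [self._fix_at_px(700.0, 500.0), self._fix_at_px(700.0, 520.0)]
        out = subject_summary("s1", "field", [], fix, [], [])
        assert out["var_fixation_x_px2"] == 0.0

    def test_known_pixel_variance(self):
        fix = [self._fix_at_px(600.0, 500.0), self._fix_at_px(800.0, 500.0)]
        out = subject_summary("s1", "field", [], fix, [], [])
        assert out["var_fixation_x_px2"] == pytest.approx(20000.0, rel=1e-9)

    def test_no_fixations_missing_not_zero(self):
        out = subject_summary("s1", "field", [], [], [], [])
        assert math.isnan(out["var_fixation_x_px2"])
        assert math.isnan(out["mean_fixation_duration_ms"])
        assert out["n_saccades"] == 0
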