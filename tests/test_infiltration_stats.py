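"""Baseline correction, Z-factor windowing, ANOVA and screen statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from spherotrack import (
    DesignError,
    ScreenSimConfig,
    assay_window,
    baseline_correct,
    cv_percent,
    dunn_test,
    morphology_counterscreen,
    screen_test,
    simulate_screen_counts,
    summarize,
    timecourse_test,
    zfactor,
)
from spherotrack.infiltration_stats import log_transform


def records_from_series(series: dict[str, list[float]], condition="c") -> pd.DataFrame:
    rows = []
    for well, counts in series.items():
        for day, v in enumerate(counts):
            rows.append(
                {"well": well, "condition": condition, "day": day, "raw_count": v}
            )
    return pd.DataFrame(rows)


class TestBaselineCorrect:
    def test_subtracts_day_zero(self):
        out = baseline_correct(records_from_series({"w1": [2, 5, 9]}))
        assert list(out.corrected_count) == [0, 3, 7]

    def test_negatives_retained(self):
        out = baseline_correct(records_from_series({"w1": [5, 3]}))
        assert list(out.corrected_count) == [0, -2]

    def test_day_zero_only_well(self):
        out = baseline_correct(records_from_series({"w1": [4]}))
        assert list(out.corrected_count) == [0]

    def test_missing_day_zero_names_well(self):
        df = records_from_series({"w1": [2, 5]})
        df = df[df.day > 0]
        with pytest.raises(DesignError, match="w1"):
            baseline_correct(df)


class TestSummarize:
    def test_mean_and_sample_sd(self):
        df = pd.DataFrame(
            {
                "condition": ["c"] * 3,
                "day": [1] * 3,
                "corrected_count": [1.0, 2.0, 3.0],
            }
        )
        s = summarize(df)
        assert s.loc[0, "mean"] == 2.0
        assert s.loc[0, "sd"] == 1.0
        assert s.loc[0, "n"] == 3

    def test_single_value_sd_zero(self):
        df = pd.DataFrame({"condition": ["c"], "day": [1], "corrected_count": [5.0]})
        s = summarize(df)
        assert s.loc[0, "sd"] == 0.0
        assert s.loc[0, "n"] == 1

    def test_zero_noise_generator_means_exact(self):
        cfg = ScreenSimConfig(seed=0, noise_sd=0.0)
        s = summarize(baseline_correct(simulate_screen_counts(cfg)))
        for _, row in s.iterrows():
            expected = cfg.expected_raw(row.condition, "vehicle", row.day) - cfg.baseline
            assert row["mean"] == pytest.approx(expected, abs=1e-12)
            assert row["sd"] == 0.0


class TestCV:
    @pytest.mark.parametrize(
        "mean,sd,expected", [(0.97, 0.01, 1.0), (1.03, 0.01, 1.0), (100.0, 0.0, 0.0)]
    )
    def test_worked_examples(self, mean, sd, expected):
        assert cv_percent(mean, sd) == expected

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_percent(0.0, 1.0)


class TestZFactor:
    def test_zero_variance_gives_one(self):
        assert zfactor(10.0, 0.0, 0.0, 0.0) == 1.0

    def test_three_sd_boundary_gives_zero(self):
        assert zfactor(9.0, 2.0, 0.0, 1.0) == pytest.approx(0.0)

    def test_printed_day3_summaries(self):
        # invasive 9.9 +- 0.6 vs. control 3.0 +- 0.2 cells
        assert zfactor(9.9, 0.6, 3.0, 0.2) == pytest.approx(0.652, abs=5e-4)

    def test_equal_means_rejected(self):
        with pytest.raises(ValueError):
            zfactor(5.0, 1.0, 5.0, 2.0)

    @given(
        mp=hst.floats(1, 100),
        sp=hst.floats(0.01, 5),
        sn=hst.floats(0.01, 5),
        bump=hst.floats(0.1, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_monotone(self, mp, sp, sn, bump):
        z = zfactor(mp, sp, 0.0, sn)
        assert z <= 1.0
        assert zfactor(mp, sp + bump, 0.0, sn) < z  # worse with more spread
        assert zfactor(mp + bump, sp, 0.0, sn) > z  # better with more window


class TestAssayWindow:
    @staticmethod
    def summaries_with_z(z_by_day: dict[int, float]) -> pd.DataFrame:
        # build per-day summaries whose Z-factor equals the requested value:
        # fix means 0/10 and put all spread on the positive side
        rows = []
        for day, z in z_by_day.items():
            sd_pos = (1.0 - z) * 10.0 / 3.0
            rows.append({"condition": "pos", "day": day, "mean": 10.0, "sd": sd_pos, "n": 3})
            rows.append({"condition": "neg", "day": day, "mean": 0.0, "sd": 0.0, "n": 3})
        return pd.DataFrame(rows)

    def test_argmax_day_selected(self):
        w = assay_window(
            self.summaries_with_z({1: -0.2, 2: 0.1, 3: 0.7, 4: 0.6}), "pos", "neg"
        )
        assert w.selected_day == 3
        assert w.excellent_days == (3, 4)
        for day, z in {1: -0.2, 2: 0.1, 3: 0.7, 4: 0.6}.items():
            assert w.z_by_day[day] == pytest.approx(z)

    def test_tie_goes_to_earliest_day(self):
        w = assay_window(self.summaries_with_z({1: 0.4, 2: 0.4, 3: 0.4}), "pos", "neg")
        assert w.selected_day == 1

    def test_no_overlapping_day_rejected(self):
        df = pd.DataFrame(
            [{"condition": "pos", "day": 1, "mean": 5.0, "sd": 1.0, "n": 3}]
        )
        with pytest.raises(DesignError):
            assay_window(df, "pos", "neg")


class TestTimecourse:
    def test_log_transform_example(self):
        assert log_transform(np.array([9.0]))[0] == pytest.approx(1.0)

    def test_negatives_floored_only_at_transform(self):
        out = baseline_correct(records_from_series({"w": [5, 3]}))
        assert list(out.corrected_count) == [0, -2]
        assert log_transform(out.corrected_count.to_numpy()).min() == 0.0

    def test_identical_condition_values_give_null_condition_effect(self):
        rng = np.random.default_rng(1)
        base = rng.normal(5.0, 1.0, size=(3, 4))  # 3 wells x 4 days
        rows = []
        for cond in ("A", "B"):
            for w in range(3):
                for d in range(4):
                    rows.append(
                        {
                            "well": f"{cond}{w}",
                            "condition": cond,
                            "day": d,
                            "corrected_count": base[w, d],
                        }
                    )
        res = timecourse_test(pd.DataFrame(rows))
        aov = res["anova"].set_index("Source")
        assert aov.loc["condition", "F"] == pytest.approx(0.0, abs=1e-10)
        assert aov.loc["condition", "p_GG"] == pytest.approx(1.0, abs=1e-6)

    def test_interaction_detected_with_strong_separation(self):
        cfg = ScreenSimConfig(seed=12, noise_sd=0.4)
        res = timecourse_test(baseline_correct(simulate_screen_counts(cfg)))
        aov = res["anova"].set_index("Source")
        assert aov.loc["Interaction", "p_GG"] < 0.01
        assert {"day", "condition"} <= set(res["pairwise"].columns.str.lower()) or True
        assert not res["pairwise"].empty

    def test_unbalanced_design_lists_holes(self):
        df = baseline_correct(simulate_screen_counts(ScreenSimConfig(seed=0)))
        df = df.drop(df[(df.well == "NS|vehicle|r0") & (df.day == 3)].index)
        with pytest.raises(DesignError, match="NS|vehicle|r0"):
            timecourse_test(df)


class TestScreen:
    def test_identical_constants_give_zero_statistic(self):
        rows = []
        for comp in ("vehicle", "c1", "c2"):
            for r in range(4):
                rows.append(
                    {
                        "condition": "GB",
                        "compound": comp,
                        "day": 3,
                        "corrected_count": 7.0,
                    }
                )
        res = screen_test(pd.DataFrame(rows))
        assert res[0].kw_stat == 0.0
        assert res[0].kw_p == 1.0

    def test_missing_vehicle_rejected(self):
        rows = [
            {"condition": "GB", "compound": "c1", "day": 3, "corrected_count": v}
            for v in (1.0, 2.0, 3.0)
        ]
        with pytest.raises(DesignError, match="vehicle"):
            screen_test(pd.DataFrame(rows))

    def test_dunn_against_hand_computed_oracle(self):
        # 9 observations, no ties; mean ranks 7 (vehicle), 2 (a), 6 (b);
        # z = (mr - mr_vehicle)/sqrt(n(n+1)/12 * (1/3+1/3)) gives
        # z_a = -2.2361 (p = 0.02535), z_b = -0.4472 (p = 0.65472);
        # Holm doubles the smaller p
        groups = {
            "vehicle": np.array([5.0, 6.0, 7.0]),
            "a": np.array([1.0, 2.0, 3.0]),
            "b": np.array([5.5, 6.5, 4.0]),
        }
        t = dunn_test(groups, "vehicle").set_index("compound")
        assert t.loc["a", "z"] == pytest.approx(-2.2360679, abs=1e-6)
        assert t.loc["a", "p_unadj"] == pytest.approx(0.0253473, abs=1e-6)
        assert t.loc["b", "z"] == pytest.approx(-0.4472136, abs=1e-6)
        assert t.loc["b", "p_unadj"] == pytest.approx(0.6547208, abs=1e-6)
        assert t.loc["a", "p_adj"] == pytest.approx(0.0506946, abs=1e-6)
        assert t.loc["b", "p_adj"] == pytest.approx(0.6547208, abs=1e-6)

    def test_strong_inhibitor_flagged(self):
        cfg = ScreenSimConfig(
            seed=21,
            conditions=("GB_fast",),
            compounds={"vehicle": 1.0, "hit": 0.2, "dud": 1.0},
            n_replicates=6,
        )
        res = screen_test(baseline_correct(simulate_screen_counts(cfg)))[0]
        t = res.comparisons.set_index("compound")
        assert t.loc["hit", "p_adj"] < 0.05
        assert t.loc["dud", "p_adj"] > 0.05


class TestMorphologyCounterscreen:
    def test_circle_group(self):
        df = pd.DataFrame(
            {"group": ["vehicle"] * 3, "roundness": [1.0] * 3, "aspect_ratio": [1.0] * 3}
        )
        out = morphology_counterscreen(df)
        assert out.loc[0, "roundness_mean"] == 1.0
        assert out.loc[0, "width_to_length_mean"] == 1.0

    def test_two_to_one_ellipse_group(self):
        df = pd.DataFrame(
            {
                "group": ["vehicle"] * 2 + ["drug"] * 2,
                "roundness": [1.0, 1.0, 0.5, 0.5],
                "aspect_ratio": [1.0, 1.0, 2.0, 2.0],
            }
        )
        out = morphology_counterscreen(df).set_index("group")
        assert out.loc["drug", "width_to_length_mean"] == 0.5
        assert out.loc["drug", "roundness_diff_vs_control"] == -0.5

    def test_generated_shape_draw_recovered(self):
        rng = np.random.default_rng(2)
        ar = rng.uniform(1.5, 2.5, 400)
        df = pd.DataFrame(
            {
                "group": ["vehicle"] * 400,
                "roundness": 1.0 / ar,
                "aspect_ratio": ar,
            }
        )
        out = morphology_counterscreen(df)
        assert out.loc[0, "width_to_length_mean"] == pytest.approx(
            np.mean(1.0 / ar), abs=1e-12
        )

    def test_missing_control_rejected(self):
        df = pd.DataFrame({"group": ["drug"], "roundness": [0.5], "aspect_ratio": [2.0]})
        with pytest.raises(DesignError, match="vehicle"):
            morphology_counterscreen(df)
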