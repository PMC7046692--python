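"""Threshold-survey summaries, the biome ANOVA, and the four-way classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nutlim.synthetic_data import gen_threshold_survey
from nutlim.thresholds_classify import (
    ClassificationRule, anova_thresholds_by_biome, classify_catchment,
    classify_table, classify_with_regional_thresholds, summarize_thresholds,
)


def _survey(thresholds, analyte="TN", biomes=None):
    n = len(thresholds)
    return pd.DataFrame({
        "study_id": [f"s{i}" for i in range(n)],
        "analyte": analyte,
        "threshold_mgL": thresholds,
        "biome": biomes if biomes is not None else ["temperate"] * n,
        "region": "US",
    })


class TestSurveySummary:
    def test_arithmetic(self):
        s = summarize_thresholds(_survey([0.2, 0.8, 1.4]), "TN")
        assert (s.mean, s.min, s.max) == (pytest.approx(0.8), 0.2, 1.4)
        assert s.se == pytest.approx(np.std([0.2, 0.8, 1.4], ddof=1) / np.sqrt(3))

    def test_repeated_value_zero_se(self):
        s = summarize_thresholds(_survey([0.5, 0.5, 0.5]), "TN")
        assert s.se == 0.0

    def test_single_study_is_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            summarize_thresholds(_survey([0.5]), "TN")

    def test_synthetic_survey_recovers_literature_means(self):
        """Survey generator centred on the global TN/TP thresholds: summary
        means land within 2 SE of 0.800 and 0.046 mg/L across seeds."""
        hits = 0
        for seed in range(10):
            survey = gen_threshold_survey(seed=seed)
            ok = True
            for analyte, target in (("TN", 0.800), ("TP", 0.046)):
                s = summarize_thresholds(survey, analyte)
                ok &= abs(s.mean - target) <= 2 * s.se
            hits += ok
        assert hits >= 8


class TestBiomeAnova:
    def test_identical_groups_f_zero(self):
        s = _survey([1.0, 2.0, 1.0, 2.0], biomes=["a", "a", "b", "b"])
        rep = anova_thresholds_by_biome(s)
        assert rep["F"] == pytest.approx(0.0)
        assert rep["p"] == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self):
        a, b = [1.1, 1.9, 1.4, 1.8], [2.6, 3.0, 2.2, 3.3]
        s = _survey(a + b, biomes=["x"] * 4 + ["y"] * 4)
        rep = anova_thresholds_by_biome(s)
        t, _ = stats.ttest_ind(a, b)
        assert rep["F"] == pytest.approx(t ** 2)

    def test_decomposition_reproduces_f(self):
        s = gen_threshold_survey(seed=5)
        rep = anova_thresholds_by_biome(s, analyte="TN")
        f_manual = (rep["ss_between"] / rep["df_between"]) / (
            rep["ss_within"] / rep["df_within"])
        assert rep["F"] == pytest.approx(f_manual)

    def test_degenerate_grouping_is_error(self):
        s = _survey([1.0, 2.0], biomes=["a", "b"])
        with pytest.raises(ValueError, match="ANOVA"):
            anova_thresholds_by_biome(s)


class TestClassifier:
    @pytest.mark.parametrize("tn,tp,expected", [
        (1.40, 0.100, 4),   # ratio 14 >= 7, TP above threshold: P-limited, undesirable
        (1.40, 0.300, 2),   # ratio 4.67 < 7, TN above threshold: N-limited, undesirable
        (0.50, 0.020, 3),   # ratio 25 >= 7, TP below threshold: P-limited, acceptable
        (0.50, 0.100, 1),   # ratio 5 < 7, TN below threshold: N-limited, acceptable
    ])
    def test_worked_examples(self, tn, tp, expected):
        assert classify_catchment(tn, tp)["type_code"] == expected

    def test_ratio_exactly_seven_is_p_limited(self):
        out = classify_catchment(0.70, 0.100)
        assert out["np_ratio"] == pytest.approx(7.0)
        assert out["limitation"] == "P"

    def test_equality_at_threshold_acceptable_by_default(self):
        assert classify_catchment(0.800, 0.300)["type_code"] == 1
        assert classify_catchment(1.0, 0.046)["type_code"] == 3

    def test_equality_configurable_to_undesirable(self):
        rule = ClassificationRule(equality_is_undesirable=True)
        assert classify_catchment(0.800, 0.300, rule)["type_code"] == 2

    def test_nonpositive_input_is_error(self):
        with pytest.raises(ValueError):
            classify_catchment(0.0, 0.1)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e3),
           st.floats(min_value=1e-6, max_value=1e3))
    def test_positive_quadrant_partition(self, tn, tp):
        out = classify_catchment(tn, tp)
        assert out["type_code"] in (1, 2, 3, 4)
        # the code is a function of (limitation, growth)
        expected = {("N", "acceptable"): 1, ("N", "undesirable"): 2,
                    ("P", "acceptable"): 3, ("P", "undesirable"): 4}
        assert out["type_code"] == expected[(out["limitation"], out["growth"])]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-4, max_value=100),
           st.floats(min_value=1e-4, max_value=100))
    def test_scale_consistency_microgram_rule(self, tn, tp):
        rule_ug = ClassificationRule(ratio_boundary=7.0, tn_threshold=800.0,
                                     tp_threshold=46.0)
        assert (classify_catchment(tn, tp)["type_code"]
                == classify_catchment(tn * 1000, tp * 1000, rule_ug)["type_code"])

    def test_raising_tn_threshold_never_moves_type1_to_type2(self):
        rng = np.random.default_rng(44)
        tn = rng.lognormal(-0.5, 1.0, 200)
        tp = rng.lognormal(-3.0, 1.0, 200)
        low = ClassificationRule(tn_threshold=0.5)
        high = ClassificationRule(tn_threshold=1.5)
        for a, b in zip(tn, tp):
            t_low = classify_catchment(a, b, low)["type_code"]
            t_high = classify_catchment(a, b, high)["type_code"]
            if t_low == 1:
                assert t_high == 1


class TestRegionalThresholds:
    preds = pd.DataFrame({
        "catchment_id": ["c1", "c2", "c3"],
        "tn_median": [0.20, 1.40, 0.50],
        "tp_median": [0.02, 0.10, 0.044],
    })
    areas = {"c1": 10.0, "c2": 20.0, "c3": 30.0}

    def test_equal_thresholds_zero_difference(self):
        regions = pd.DataFrame({"region": ["R"], "tn_threshold": [0.800],
                                "tp_threshold": [0.046]})
        rep = classify_with_regional_thresholds(
            self.preds, regions, {c: "R" for c in self.areas}, self.areas)
        assert (rep["difference"]["percent_difference"] == 0).all()

    def test_willamette_example_same_type_both_rules(self):
        regions = pd.DataFrame({"region": ["I"], "tn_threshold": [0.310],
                                "tp_threshold": [0.047]})
        rep = classify_with_regional_thresholds(
            self.preds.head(1), regions, {"c1": "I"}, self.areas)
        assert rep["regional"]["type_code"].iloc[0] == 3
        assert rep["global"]["type_code"].iloc[0] == 3

    def test_stricter_regional_tp_flips_type3_to_4(self):
        regions = pd.DataFrame({"region": ["strict"], "tn_threshold": [0.800],
                                "tp_threshold": [0.040]})
        rep = classify_with_regional_thresholds(
            self.preds, regions, {c: "strict" for c in self.areas}, self.areas)
        flipped = rep["regional"].merge(
            rep["global"][["catchment_id", "type_code"]],
            on="catchment_id", suffixes=("_reg", "_glob"))
        moved = flipped.loc[(flipped["type_code_glob"] == 3)
                            & (flipped["type_code_reg"] == 4)]
        assert list(moved["catchment_id"]) == ["c3"]  # TP 0.044 straddles
        d = rep["difference"]
        row4 = d.loc[(d["region"] == "all") & (d["type_code"] == 4)].iloc[0]
        assert row4["area_regional_km2"] > row4["area_global_km2"]

    def test_partial_thresholds_are_error(self):
        regions = pd.DataFrame({"region": ["bad"], "tn_threshold": [0.800],
                                "tp_threshold": [np.nan]})
        with pytest.raises(ValueError, match="partial"):
            classify_with_regional_thresholds(
                self.preds, regions, {c: "bad" for c in self.areas}, self.areas)

    def test_missing_region_exclude_mode(self):
        regions = pd.DataFrame({"region": ["R"], "tn_threshold": [0.800],
                                "tp_threshold": [0.046]})
        rep = classify_with_regional_thresholds(
            self.preds, regions, {"c1": "R"}, self.areas, missing_region="exclude")
        assert list(rep["regional"]["catchment_id"]) == ["c1"]


def test_classify_table_matches_rowwise():
    rng = np.random.default_rng(9)
    preds = pd.DataFrame({
        "catchment_id": [f"c{i}" for i in range(30)],
        "tn_median": rng.lognormal(-0.5, 1, 30),
        "tp_median": rng.lognormal(-3, 1, 30),
    })
    table = classify_table(preds)
    for _, row in table.iterrows():
        single = classify_catchment(row["tn_median"], row["tp_median"])
        assert single["type_code"] == row["type_code"]
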