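"""Biomarker aggregation, rank-sum tests, Bonferroni tiers, ANOVA letters."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snailheat.physiology import (
    anova_tukey,
    bonferroni_thresholds,
    bonferroni_tier,
    hsp70_percent_of_control,
    integrity_ratio,
    max_induction,
    mean_assessment_value,
    rank_sum_test,
    summarize,
    validate_physiology,
    wilcoxon_vs_control,
)
from conftest import make_records


def _hsp_frame(profile: dict[int, list[float]], pop="1") -> pd.DataFrame:
    rows = []
    for t, values in profile.items():
        for k, v in enumerate(values):
            rows.append({
                "individual_id": f"{pop}_{t}_{k}", "population_id": pop,
                "temperature": t, "hsp70_rel": v, "tubule_score": np.nan,
                "digestive_score": np.nan, "calcium_score": np.nan,
            })
    return pd.DataFrame(rows)


class TestMav:
    def test_all_ones(self):
        df = make_records({"1": [1] * 8}, "tubule_score", 25)
        assert mean_assessment_value(df, "1", 25, "tubule") == (1.0, 0.0)

    def test_hand_computed_mean_and_sd(self):
        scores = [4, 5, 5, 5, 5, 5, 5, 5]
        df = make_records({"1": scores}, "digestive_score", 40)
        mean, sd = mean_assessment_value(df, "1", 40, "digestive")
        assert mean == pytest.approx(4.875)
        assert sd == pytest.approx(math.sqrt(0.125))

    def test_empty_cell_is_named(self):
        df = make_records({"1": [2, 3]}, "tubule_score", 25)
        with pytest.raises(ValueError, match="calcium_score.*'1'.*40"):
            mean_assessment_value(df, "1", 40, "calcium")

    @given(st.lists(st.integers(1, 5), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_mav_within_score_bounds(self, scores):
        df = make_records({"1": scores}, "calcium_score", 33)
        mean, _ = mean_assessment_value(df, "1", 33, "calcium")
        assert 1.0 <= mean <= 5.0


class TestPercentOfControl:
    def test_equal_means_are_100(self):
        df = _hsp_frame({25: [1.0, 1.0], 40: [1.0, 1.0]})
        pct = hsp70_percent_of_control(df, "1")
        assert pct[40] == pytest.approx(100.0)

    def test_reproduces_printed_induction_values(self):
        # constructed group means: the ratio formula behind the reported
        # maxima (193.9% at 40 °C, 104.2% at 38 °C)
        df = _hsp_frame({25: [1.0] * 10, 38: [1.042] * 10, 40: [1.939] * 10})
        pct = hsp70_percent_of_control(df, "1")
        assert pct[40] == pytest.approx(193.9)
        assert pct[38] == pytest.approx(104.2)

    def test_missing_control_errors(self):
        df = _hsp_frame({40: [1.0]})
        with pytest.raises(ValueError, match="control"):
            hsp70_percent_of_control(df, "1")


class TestMaxInduction:
    def test_unimodal_profile_peaks_at_40(self):
        df = _hsp_frame({25: [1.0] * 4, 33: [1.2] * 4, 40: [1.9] * 4,
                         48: [0.8] * 4})
        assert max_induction(df, "1") == (40, pytest.approx(190.0))

    def test_flat_profile_tie_breaks_to_lowest_temperature(self):
        df = _hsp_frame({25: [1.0] * 4, 33: [1.0] * 4, 40: [1.0] * 4})
        t, pct = max_induction(df, "1")
        assert (t, pct) == (33, pytest.approx(100.0))

    def test_high_strategy_synthetic_population(self, phys_df):
        # strategy-2 archetype: maximum induction within the planted band
        t, pct = max_induction(phys_df, "3")
        assert t in (38, 40)
        assert 145.0 <= pct <= 205.0


class TestIntegrityRatio:
    def test_equal_mavs_is_one(self):
        df = pd.concat([
            make_records({"1": [2, 2]}, "digestive_score", 40),
            make_records({"1": [2, 2]}, "calcium_score", 40),
        ])
        assert integrity_ratio(df, "1", 40) == pytest.approx(1.0)

    def test_half_ratio(self):
        df = pd.concat([
            make_records({"1": [2, 2]}, "digestive_score", 40),
            make_records({"1": [4, 4]}, "calcium_score", 40),
        ])
        assert integrity_ratio(df, "1", 40) == pytest.approx(0.5)

    @given(st.lists(st.integers(1, 5), min_size=2, max_size=8),
           st.lists(st.integers(1, 5), min_size=2, max_size=8))
    @settings(max_examples=40, deadline=None)
    def test_ratio_bounded_by_score_range(self, dig, cal):
        df = pd.concat([
            make_records({"1": dig}, "digestive_score", 40),
            make_records({"1": cal}, "calcium_score", 40),
        ])
        assert 0.2 <= integrity_ratio(df, "1", 40) <= 5.0


def _perm_oracle(x, y):
    """Exhaustive enumeration of group assignments (independent oracle)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2
    obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        count += abs(u - mu) >= abs(obs - mu) - 1e-9
    return count / total


class TestRankSum:
    def test_identical_groups_p_one(self):
        df = _hsp_frame({25: [1.0, 1.0, 1.0], 40: [1.0, 1.0, 1.0]})
        assert wilcoxon_vs_control(df, "1", "hsp70_rel", 40) == 1.0

    def test_extreme_separation_exact_enumeration(self):
        # all ranks disjoint: 2 of C(8,4)=70 assignments are as extreme
        p = rank_sum_test(np.array([1, 1, 1, 1]), np.array([5, 5, 5, 5]))
        assert p == pytest.approx(2 / 70)
        assert p == pytest.approx(_perm_oracle([1, 1, 1, 1], [5, 5, 5, 5]))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_permutation_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(1, 6, size=8).astype(float)
        y = np.clip(x + rng.integers(-1, 3, size=8), 1, 5).astype(float)
        if np.all(np.concatenate([x, y]) == x[0]):
            y[0] = x[0] % 5 + 1
        assert rank_sum_test(x, y) == pytest.approx(_perm_oracle(x, y), abs=1e-9)

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        y = rng.normal(0.5, size=60)
        p = rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert p == pytest.approx(ref)

    def test_pvalues_in_unit_interval(self, phys_df):
        for temp in (33, 40, 48):
            p = wilcoxon_vs_control(phys_df, "4", "hsp70_rel", temp)
            assert 0.0 <= p <= 1.0


class TestBonferroniTier:
    @pytest.mark.parametrize("p,m,expected", [
        (0.01, 4, "*"),        # 0.0025 < 0.01 <= 0.0125
        (0.0017, 6, "**"),     # boundary inclusive
        (0.5, 4, "ns"),
        (0.0125, 4, "*"),      # upper boundary inclusive
        (0.0126, 4, "ns"),
        (0.00025, 4, "***"),
        (0.0005, 4, "**"),
    ])
    def test_half_open_tiers(self, p, m, expected):
        assert bonferroni_tier(p, m) == expected

    def test_printed_threshold_sets_digit_for_digit(self):
        t4 = bonferroni_thresholds(4)
        assert (round(t4[0], 4), round(t4[1], 4), round(t4[2], 5)) == (
            0.0125, 0.0025, 0.00025
        )
        t6 = bonferroni_thresholds(6)
        assert (round(t6[0], 4), round(t6[1], 4), round(t6[2], 5)) == (
            0.0083, 0.0017, 0.00017
        )

    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 10))
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_p(self, p1, p2, m):
        order = ["***", "**", "*", "ns"]
        lo, hi = sorted((p1, p2))
        assert order.index(bonferroni_tier(lo, m)) <= order.index(
            bonferroni_tier(hi, m)
        )


class TestAnovaTukey:
    def test_equal_group_means_give_zero_f(self):
        df = make_records({"1": [2, 2, 2], "2": [2, 2, 2]}, "hsp70_rel", 40)
        res = anova_tukey(df, "hsp70_rel", temperature=40)
        assert res.f_statistic == 0.0
        assert set(res.letters.values()) == {"a"}

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a = rng.normal(1.0, 0.2, 10)
        b = rng.normal(1.5, 0.2, 10)
        df = make_records({"1": a.tolist(), "2": b.tolist()}, "hsp70_rel", 40)
        res = anova_tukey(df, "hsp70_rel", temperature=40)
        t, _ = stats.ttest_ind(a, b)  # pooled-variance t
        assert res.f_statistic == pytest.approx(t**2)

    def test_synthetic_40C_separates_flat_population(self, phys_df):
        res = anova_tukey(phys_df, "hsp70_rel", temperature=40)
        high_pops = {"3", "6", "7"}
        flat_letters = set(res.letters["4"])
        for pop in high_pops:
            assert not flat_letters & set(res.letters[pop])

    def test_single_group_errors(self):
        df = make_records({"1": [1, 2, 3]}, "hsp70_rel", 40)
        with pytest.raises(ValueError, match="2 groups"):
            anova_tukey(df, "hsp70_rel", temperature=40)


class TestSummarize:
    def test_summary_consistency(self, phys_df):
        summary = summarize(phys_df)
        row = summary[(summary["population_id"] == "1")
                      & (summary["temperature"] == 25)].iloc[0]
        assert row["hsp70_n"] == 10
        assert row["mav_tubule_n"] == 8
        assert row["hsp70_percent_of_control"] == pytest.approx(100.0)
        assert row["integrity_ratio"] == pytest.approx(
            row["mav_digestive"] / row["mav_calcium"]
        )

    def test_validation_rejects_bad_inputs(self, phys_df):
        bad = phys_df.copy()
        bad.loc[0, "temperature"] = 99
        with pytest.raises(ValueError, match="temperatures"):
            validate_physiology(bad)
        bad = phys_df.copy()
        bad.loc[0, "tubule_score"] = 7
        with pytest.raises(ValueError, match="1-5"):
            validate_physiology(bad)
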