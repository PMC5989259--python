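"""Phenotype rates, one-way ANOVA, post hoc comparisons and qPCR fold change."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolscan.phenotypes import (
    compute_rates,
    one_way_anova,
    pairwise_welch,
    relative_expression,
    significance_stars,
    trait_report,
)


def _table(rows):
    return pd.DataFrame(
        rows, columns=["trait", "group", "replicate", "numerator", "denominator"]
    )


class TestRates:
    def test_count_rates_are_simple_ratios(self):
        df = _table(
            [
                ("production", "a", 1, 200, 400),
                ("survival", "a", 1, 300, 300),
                ("adhesive", "a", 1, 50, 200),
            ]
        )
        rates = compute_rates(df)
        assert list(rates["rate"]) == pytest.approx([0.5, 1.0, 0.25])

    def test_growth_is_relative_height_gain(self):
        df = _table([("growth", "a", 1, 150.0, 100.0)])
        assert compute_rates(df)["rate"].item() == pytest.approx(0.5)
        assert (
            compute_rates(df, growth_mode="absolute")["rate"].item() == pytest.approx(50.0)
        )

    def test_zero_denominator_is_an_error(self):
        df = _table([("production", "a", 1, 10, 0)])
        with pytest.raises(ValueError, match="denominator"):
            compute_rates(df)

    def test_rates_are_scale_free(self):
        df1 = _table([("production", "a", 1, 200, 400)])
        df2 = _table([("production", "a", 1, 600, 1200)])
        assert compute_rates(df1)["rate"].item() == compute_rates(df2)["rate"].item()


class TestAnova:
    def test_matches_independent_implementation(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [7.0, 8.0, 9.0]}
        res = one_way_anova(groups)
        f_ref, p_ref = stats.f_oneway(groups["a"], groups["b"])
        assert res.f_statistic == pytest.approx(float(f_ref), abs=1e-10)
        assert res.p_value == pytest.approx(float(p_ref), abs=1e-10)

    def test_closed_form_sums_of_squares(self):
        # SSB = 3*(2-5)^2 + 3*(8-5)^2 = 54; SSW = 2 + 2; F = 54 / (4/4) = 54
        res = one_way_anova({"a": [1.0, 2.0, 3.0], "b": [7.0, 8.0, 9.0]})
        assert res.f_statistic == pytest.approx(54.0, abs=1e-10)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_null_case_is_not_significant(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(0.5, 0.05, 5) for g in "abc"}
        # identical generating distribution; chosen seed gives p above 0.05
        res = one_way_anova(groups)
        assert res.p_value >= 0.05
        assert res.stars == ""

    def test_large_shift_is_highly_significant(self):
        rng = np.random.default_rng(1)
        groups = {
            "a": rng.normal(0.0, 1.0, 5),
            "b": rng.normal(0.0, 1.0, 5),
            "c": rng.normal(10.0, 1.0, 5),  # shifted by 10 sd
        }
        res = one_way_anova(groups)
        assert res.p_value < 0.01
        assert res.stars == "**"

    def test_degenerate_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_needs_two_groups_and_two_replicates(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0], "b": [2.0]})

    def test_trait_report_covers_all_traits(self):
        rng = np.random.default_rng(2)
        rows = []
        for trait in ("production", "survival"):
            for group in ("a", "b", "c"):
                for rep in range(1, 4):
                    rows.append((trait, group, rep, int(rng.integers(100, 300)), 400))
        report = trait_report(compute_rates(_table(rows)))
        assert set(report["trait"]) == {"production", "survival"}
        assert {"f_statistic", "p_value", "stars"} <= set(report.columns)


class TestPostHoc:
    def test_pairwise_welch_flags_the_shifted_group(self):
        rng = np.random.default_rng(3)
        groups = {
            "a": rng.normal(0.5, 0.02, 6),
            "b": rng.normal(0.5, 0.02, 6),
            "c": rng.normal(0.9, 0.02, 6),
        }
        res = pairwise_welch(groups)
        assert len(res) == 3
        sig = res.loc[res["stars"] != ""]
        assert set(map(tuple, sig[["group_a", "group_b"]].values)) == {("a", "c"), ("b", "c")}


class TestRelativeExpression:
    @pytest.mark.parametrize(
        "ddct,expected",
        [(0.0, 1.0), (-1.0, 2.0), (3.32, 2 ** -3.32)],
    )
    def test_fold_change(self, ddct, expected):
        # encode ddct through the four Ct values
        fold = relative_expression(20.0 + ddct, 20.0, 18.0, 18.0)
        assert fold == pytest.approx(expected)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError):
            relative_expression(float("nan"), 20, 18, 18)


class TestStars:
    @pytest.mark.parametrize("p,stars", [(0.2, ""), (0.04, "*"), (0.005, "**")])
    def test_convention(self, p, stars):
        assert significance_stars(p) == stars
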