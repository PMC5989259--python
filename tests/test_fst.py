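"""Hudson F_ST components, window aggregation, and top-fraction selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poolscan.fst import (
    select_top_windows,
    site_fst_components,
    sites_fst,
    window_fst,
)

from .conftest import make_site_table


def brute_force_window_fst(positions, nums, dens, window_size):
    """Independent re-derivation: dict-of-sums per window, pure Python."""
    acc = {}
    for pos, n, d in zip(positions, nums, dens):
        w = pos // window_size
        a = acc.setdefault(w, [0.0, 0.0, 0])
        a[0] += n
        a[1] += d
        a[2] += 1
    return {w: (a[0] / a[1] if a[1] > 0 else float("nan")) for w, a in acc.items()}


def _component_table(positions, p1s, p2s, n=40, scaffold="scaffold1"):
    num, den = site_fst_components(np.array(p1s), n, np.array(p2s), n)
    return pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos": positions,
            "p1": p1s,
            "p2": p2s,
            "n1": n,
            "n2": n,
            "fst_num": num,
            "fst_den": den,
        }
    )


class TestSiteComponents:
    def test_no_differentiation_has_nonpositive_numerator(self):
        num, _ = site_fst_components(0.3, 40, 0.3, 40)
        assert num <= 0

    def test_fixation_limit_approaches_one(self):
        num, den = site_fst_components(1.0, 10_000, 0.0, 10_000)
        assert num / den == pytest.approx(1.0, abs=1e-3)

    def test_known_value_from_the_estimator_formula(self):
        # direct evaluation: (0.8)^2 - 2*0.09/39 over 0.9*0.9 + 0.1*0.1
        num, den = site_fst_components(0.9, 40, 0.1, 40)
        assert num / den == pytest.approx(0.775, abs=5e-4)

    def test_small_sample_size_rejected(self):
        with pytest.raises(ValueError):
            site_fst_components(0.5, 1, 0.5, 40)

    def test_label_swap_invariance(self):
        num1, den1 = site_fst_components(0.8, 30, 0.2, 50)
        num2, den2 = site_fst_components(0.2, 50, 0.8, 30)
        assert num1 == pytest.approx(num2)
        assert den1 == pytest.approx(den2)

    def test_nei_estimator_available(self):
        num, den = site_fst_components(0.9, 40, 0.1, 40, estimator="nei")
        # Ht = 0.5, Hs = 0.18
        assert num / den == pytest.approx((0.5 - 0.18) / 0.5)


class TestSitesFst:
    def test_effective_size_is_capped_by_pool_chromosomes(self):
        sites = make_site_table(
            [("scaffold1", 10, "A", "C", 30.0, {"a": (200, 100), "b": (10, 10)})],
            pools=("a", "b"),
        )
        comp = sites_fst(sites, "a", "b", pool_size=46)
        assert comp.loc[0, "n1"] == 92  # min(2*46, 300)
        assert comp.loc[0, "n2"] == 20


class TestWindows:
    def test_single_site_window_equals_site_ratio(self):
        tbl = _component_table([150], [0.9], [0.1])
        w = window_fst(tbl, 1000)
        assert len(w) == 1
        assert w.loc[0, "fst_raw"] == pytest.approx(
            tbl.loc[0, "fst_num"] / tbl.loc[0, "fst_den"]
        )
        assert (w.loc[0, "start"], w.loc[0, "end"]) == (0, 1000)

    def test_two_sites_aggregate_as_ratio_of_sums(self):
        tbl = _component_table([100, 900], [0.9, 0.6], [0.1, 0.4])
        w = window_fst(tbl, 1000)
        expected = (tbl["fst_num"].sum()) / (tbl["fst_den"].sum())
        assert w.loc[0, "fst_raw"] == pytest.approx(expected, abs=1e-15)

    def test_no_differentiation_windows_are_nonpositive(self):
        tbl = _component_table([100, 1100, 2100], [0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
        w = window_fst(tbl, 1000)
        assert (w["fst_raw"] <= 0).all()
        assert (w["fst"] == 0).all()  # display floor

    def test_unsorted_input_rejected(self):
        tbl = _component_table([900, 100], [0.9, 0.6], [0.1, 0.4])
        with pytest.raises(ValueError, match="sorted"):
            window_fst(tbl, 1000)

    def test_empty_windows_emitted_but_not_ranked(self):
        tbl = _component_table([150], [0.9], [0.1])
        w = window_fst(tbl, 1000, scaffold_lengths={"scaffold1": 3000})
        assert len(w) == 3
        assert w["rank"].notna().sum() == 1

    @given(
        st.lists(
            st.tuples(st.integers(0, 19_999), st.floats(0, 1), st.floats(0, 1)),
            min_size=1,
            max_size=20,
            unique_by=lambda t: t[0],
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_window_fst_matches_brute_force(self, site_specs):
        site_specs = sorted(site_specs)
        positions = [s[0] for s in site_specs]
        p1s = [s[1] for s in site_specs]
        p2s = [s[2] for s in site_specs]
        tbl = _component_table(positions, p1s, p2s)
        w = window_fst(tbl, 1000)
        oracle = brute_force_window_fst(
            positions, tbl["fst_num"], tbl["fst_den"], 1000
        )
        for row in w.itertuples(index=False):
            expected = oracle[row.start // 1000]
            if math.isnan(expected):
                assert math.isnan(row.fst_raw)
            else:
                assert abs(row.fst_raw - expected) < 1e-12


class TestTopWindows:
    def _uniform_windows(self, n, fst=0.5):
        tbl = _component_table(
            [i * 1000 + 500 for i in range(n)],
            [0.9] * n,
            [0.1] * n,
        )
        return window_fst(tbl, 1000)

    def test_one_percent_of_thousand_is_ten(self):
        w = self._uniform_windows(1000)
        top = select_top_windows(w, 0.01)
        assert len(top) == 10

    def test_ceil_rule(self):
        w = self._uniform_windows(101)
        assert len(select_top_windows(w, 0.01)) == 2  # ceil(1.01)

    def test_ties_resolved_by_coordinate_order(self):
        w = self._uniform_windows(50)  # all equal F_ST
        top = select_top_windows(w, 0.1)
        assert len(top) == 5
        assert list(top["start"]) == [0, 1000, 2000, 3000, 4000]

    def test_empty_ranking_is_an_error(self):
        tbl = _component_table([150], [0.9], [0.1])
        w = window_fst(tbl, 1000, scaffold_lengths={"scaffold1": 3000}, min_snps=5)
        with pytest.raises(ValueError):
            select_top_windows(w, 0.01)

    def test_planted_high_divergence_windows_rank_first(self):
        # 99 background windows at p1 ~ p2, one strongly diverged window
        n = 100
        p1 = [0.5] * (n - 1) + [0.95]
        p2 = [0.5] * (n - 1) + [0.05]
        tbl = _component_table([i * 1000 + 500 for i in range(n)], p1, p2)
        w = window_fst(tbl, 1000)
        top = select_top_windows(w, 0.01)
        assert list(top["start"]) == [(n - 1) * 1000]
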