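"""Larval phenotype rates, one-way ANOVA group comparison, qPCR fold change.

The four assayed traits are rates: larval production (D-stage larvae per
egg), survival (survivors per starting D-larva), growth (relative shell
height gain) and adhesion (adherent per eye-spot larva).  Groups are
compared with a classical one-way ANOVA (between/within mean-square
ratio); pairwise Welch t-tests with Benjamini–Hochberg adjustment serve
as post hoc comparisons.  Relative expression uses the standard
2^-ΔΔCt quantity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

COUNT_TRAITS = ("production", "survival", "adhesive")


def compute_rates(table: pd.DataFrame, growth_mode: str = "relative") -> pd.DataFrame:
    """Per-replicate rates from a trait table.

    ``table`` columns: ``trait, group, replicate, numerator, denominator``.
    Count traits: rate = numerator / denominator.  Growth: numerator and
    denominator are mean shell heights after/before; the default
    ``relative`` mode returns (after - before) / before, ``absolute``
    returns after - before.
    """
    if growth_mode not in {"relative", "absolute"}:
        raise ValueError(f"unknown growth_mode {growth_mode!r}")
    if (table["denominator"] <= 0).any():
        bad = table.loc[table["denominator"] <= 0].iloc[0]
        raise ValueError(f"zero denominator for {bad['trait']}/{bad['group']} replicate {bad['replicate']}")
    out = table.copy()
    num = out["numerator"].astype(float)
    den = out["denominator"].astype(float)
    rate = num / den
    growth = out["trait"] == "growth"
    if growth_mode == "relative":
        rate[growth] = (num[growth] - den[growth]) / den[growth]
    else:
        rate[growth] = num[growth] - den[growth]
    out["rate"] = rate
    count_rows = out["trait"].isin(COUNT_TRAITS)
    if ((out.loc[count_rows, "rate"] < 0) | (out.loc[count_rows, "rate"] > 1)).any():
        raise ValueError("count-based rates must lie in [0, 1]")
    return out


def significance_stars(p: float) -> str:
    """"**" for p < 0.01, "*" for p < 0.05, otherwise empty."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    stars: str


def one_way_anova(groups: Mapping[str, Sequence[float]] | pd.DataFrame) -> AnovaResult:
    """Classical one-way ANOVA from explicit sums of squares.

    Accepts either ``{group: values}`` or a DataFrame with ``group`` and
    ``rate`` columns.  Requires >= 2 groups with >= 2 replicates each and
    non-zero within-group variance.
    """
    if isinstance(groups, pd.DataFrame):
        groups = {g: sub["rate"].to_numpy(dtype=float) for g, sub in groups.groupby("group")}
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 2 for v in arrays.values()):
        raise ValueError("need at least two replicates per group")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df_b = len(arrays) - 1
    df_w = len(all_vals) - len(arrays)
    if ss_within == 0:
        raise ValueError("zero within-group variance: F statistic undefined")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w, significance_stars(p))


def pairwise_welch(groups: Mapping[str, Sequence[float]] | pd.DataFrame) -> pd.DataFrame:
    """Post hoc pairwise Welch t-tests, BH-adjusted across pairs."""
    if isinstance(groups, pd.DataFrame):
        groups = {g: sub["rate"].to_numpy(dtype=float) for g, sub in groups.groupby("group")}
    pairs = sorted(combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append((a, b, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "t_statistic", "p_value"])
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["stars"] = [significance_stars(p) for p in out["p_adjusted"]]
    return out


def trait_report(rates: pd.DataFrame) -> pd.DataFrame:
    """Omnibus ANOVA per trait over a rate table with post hoc stars."""
    rows = []
    for trait, sub in rates.groupby("trait"):
        res = one_way_anova(sub)
        rows.append((trait, res.f_statistic, res.p_value, res.df_between, res.df_within, res.stars))
    return pd.DataFrame(
        rows, columns=["trait", "f_statistic", "p_value", "df_between", "df_within", "stars"]
    )


def relative_expression(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """qPCR fold change 2^-ΔΔCt between a test and a control condition."""
    cts = (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
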