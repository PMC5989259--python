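"""Per-site and windowed F_ST between two pools, with top-fraction outlier selection.

The default estimator is Hudson-type with a finite-sample correction:

.. math::

    \\hat N = (p_1 - p_2)^2 - \\frac{p_1(1-p_1)}{n_1 - 1}
                            - \\frac{p_2(1-p_2)}{n_2 - 1}, \\qquad
    \\hat D = p_1(1-p_2) + p_2(1-p_1)

with the window value the ratio of summed numerators to summed
denominators ("ratio of averages"), which is far less noisy than averaging
per-site ratios.  The per-pool effective sample size is
``min(2 * pool_size, depth)``: pooled reads cannot carry more information
than the chromosomes in the pool.  A Nei/Wright-style estimator (no
finite-sample correction) is available for sensitivity checks.

Negative site numerators (sampling noise under no differentiation) are
retained in window sums so the ranking is unbiased; the reported window
value is floored at zero for display, ranking uses the raw ratio.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

ESTIMATORS = ("hudson", "nei")


def site_fst_components(p1, n1, p2, n2, estimator: str = "hudson"):
    """Numerator and denominator of the site F_ST estimator (vectorised).

    ``p1, p2`` are alternate-allele frequencies, ``n1, n2`` effective
    sample sizes (chromosomes).  The Hudson form requires ``n > 1``.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if estimator == "hudson":
        if np.any(n1 <= 1) or np.any(n2 <= 1):
            raise ValueError("Hudson correction requires effective sample sizes > 1")
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    elif estimator == "nei":
        pbar = (p1 + p2) / 2
        ht = 2 * pbar * (1 - pbar)
        hs = p1 * (1 - p1) + p2 * (1 - p2)
        num = ht - hs
        den = ht
    else:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    return num, den


def sites_fst(
    sites: pd.DataFrame,
    pop_a: str,
    pop_b: str,
    pool_size: int,
    estimator: str = "hudson",
) -> pd.DataFrame:
    """Site-level F_ST components for a pair of pools.

    Effective sample size per pool = min(2 * pool_size, read depth).
    Returns ``scaffold, pos, p1, p2, n1, n2, fst_num, fst_den``.
    """
    for pop in (pop_a, pop_b):
        if f"{pop}.ref" not in sites.columns:
            raise KeyError(f"pool {pop!r} absent from site table")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    d1 = sites[f"{pop_a}.ref"].to_numpy() + sites[f"{pop_a}.alt"].to_numpy()
    d2 = sites[f"{pop_b}.ref"].to_numpy() + sites[f"{pop_b}.alt"].to_numpy()
    if np.any(d1 < 1) or np.any(d2 < 1):
        raise ValueError("zero-depth sites present; filter first")
    p1 = sites[f"{pop_a}.alt"].to_numpy() / d1
    p2 = sites[f"{pop_b}.alt"].to_numpy() / d2
    n1 = np.minimum(2 * pool_size, d1)
    n2 = np.minimum(2 * pool_size, d2)
    num, den = site_fst_components(p1, n1, p2, n2, estimator=estimator)
    out = pd.DataFrame(
        {
            "scaffold": sites["scaffold"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "p1": p1,
            "p2": p2,
            "n1": n1,
            "n2": n2,
            "fst_num": num,
            "fst_den": den,
        }
    )
    return out.sort_values(["scaffold", "pos"], kind="mergesort").reset_index(drop=True)


def window_fst(
    site_table: pd.DataFrame,
    window_size: int = 1000,
    scaffold_lengths: Mapping[str, int] | None = None,
    min_snps: int = 1,
) -> pd.DataFrame:
    """Aggregate site components into non-overlapping tiling windows.

    Window boundaries sit at multiples of ``window_size`` from each
    scaffold start.  The window value is sum(num)/sum(den).  Windows with
    fewer than ``min_snps`` SNPs are kept in the table (when scaffold
    lengths are given, empty windows are emitted too) but excluded from
    ranking: their ``rank`` is NA.  Ranks are dense over ranked windows,
    highest raw F_ST first, ties broken by (scaffold, start).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    st = site_table
    sorted_ok = (
        st.groupby("scaffold", sort=False)["pos"].apply(lambda s: bool(s.is_monotonic_increasing)).all()
        if len(st)
        else True
    )
    if not sorted_ok:
        raise ValueError("site table must be sorted by position within scaffolds")
    win_idx = st["pos"].to_numpy() // window_size
    grouped = (
        st.assign(widx=win_idx)
        .groupby(["scaffold", "widx"], sort=False)
        .agg(n_snps=("pos", "size"), num=("fst_num", "sum"), den=("fst_den", "sum"))
        .reset_index()
    )
    rows = {
        (r.scaffold, int(r.widx)): (int(r.n_snps), float(r.num), float(r.den))
        for r in grouped.itertuples(index=False)
    }
    if scaffold_lengths:
        all_keys = [
            (scaf, w)
            for scaf, L in scaffold_lengths.items()
            for w in range(math.ceil(L / window_size))
        ]
    else:
        all_keys = sorted(rows)
    records = []
    for scaf, w in sorted(all_keys):
        n, num, den = rows.get((scaf, w), (0, 0.0, 0.0))
        raw = num / den if (n > 0 and den > 0) else np.nan
        end = (w + 1) * window_size
        if scaffold_lengths and scaf in scaffold_lengths:
            end = min(end, scaffold_lengths[scaf])
        records.append((scaf, w * window_size, end, n, raw))
    out = pd.DataFrame(records, columns=["scaffold", "start", "end", "n_snps", "fst_raw"])
    out["fst"] = out["fst_raw"].clip(lower=0.0)
    ranked = (out["n_snps"] >= min_snps) & out["fst_raw"].notna()
    order = out.loc[ranked].sort_values(
        ["fst_raw", "scaffold", "start"], ascending=[False, True, True], kind="mergesort"
    )
    out["rank"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out.loc[order.index, "rank"] = np.arange(1, len(order) + 1)
    return out


def select_top_windows(windows: pd.DataFrame, fraction: float = 0.01) -> pd.DataFrame:
    """The highest-F_ST fraction of ranked windows.

    Selects ``k = ceil(fraction * n_ranked)`` windows; ties at the cutoff
    are already resolved deterministically by the (scaffold, start) order
    baked into the ranks.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    ranked = windows.loc[windows["rank"].notna()]
    if ranked.empty:
        raise ValueError("no ranked windows to select from")
    k = math.ceil(fraction * len(ranked))
    sel = ranked.loc[ranked["rank"] <= k].copy()
    sel = sel.sort_values("rank", kind="mergesort").reset_index(drop=True)
    sel["is_outlier"] = True
    return sel


def write_windows_bed(windows: pd.DataFrame, path) -> None:
    """Outlier windows as BED (already 0-based half-open)."""
    with open(path, "w") as fh:
        for r in windows.sort_values(["scaffold", "start"]).itertuples(index=False):
            fh.write(f"{r.scaffold}\t{int(r.start)}\t{int(r.end)}\t{r.fst:.6g}\n")
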