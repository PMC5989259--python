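"""Windowed F_ST scan: 1-kb tiling windows, top 1% selected as outliers.

Hudson-type estimator aggregated as ratio-of-sums per window; effective
per-pool sample size min(2 x 46, depth).  Reports where the planted sweep
windows rank.
"""

import pandas as pd
from common import STUDY_PARAMS, TABLES, require

from poolscan.fst import select_top_windows, sites_fst, window_fst, write_windows_bed
from poolscan.simulate import simulate_population_frequencies


def main() -> None:
    filtered = require(TABLES / "filtered_sites.tsv", "analysis/02_filter_sites.py")
    sites = pd.read_csv(filtered, sep="\t")
    truth = simulate_population_frequencies(STUDY_PARAMS)
    planted = truth.loci[truth.loci["is_outlier"]]
    sweep_windows = {(s, p // 1000) for s, p in zip(planted["scaffold"], planted["pos"])}

    for treatment in ("hypo", "hyper"):
        comp = sites_fst(sites, treatment, "control",
                         pool_size=STUDY_PARAMS.pool_size)
        windows = window_fst(comp, 1000, STUDY_PARAMS.scaffold_lengths)
        windows.to_csv(TABLES / f"windows_{treatment}.tsv", sep="\t", index=False)
        top = select_top_windows(windows, 0.01)
        write_windows_bed(top, TABLES / f"outlier_windows_{treatment}.bed")
        ranked = windows["rank"].notna().sum()
        bg_mean = windows.loc[windows["rank"].notna(), "fst_raw"].mean()
        print(f"{treatment} vs control: {ranked} ranked windows, "
              f"mean F_ST {bg_mean:.4f}, top 1% = {len(top)} windows")
        if treatment == STUDY_PARAMS.outlier_pool:
            top_keys = {(s, st // 1000) for s, st in zip(top["scaffold"], top["start"])}
            got = len(sweep_windows & top_keys)
            print(f"  sweep windows in the top 1%: {got}/{len(sweep_windows)}")


if __name__ == "__main__":
    main()
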