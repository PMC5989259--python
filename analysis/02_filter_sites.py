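"""Apply the SNP site filters to the pooled calls and account for removals.

Rules (in attribution order): per-pool depth >= 2 (>= 3 where a pool shows
both alleles), depth <= 3x the pool's mean, base quality >= 20, outside
the SSR mask.  Writes the filtered table and a per-rule removal report.
"""

import pandas as pd
from common import STUDY_DIR, TABLES, require

from poolscan.io import FilterParams, apply_site_filters, read_mask, read_pool_sites


def main() -> None:
    vcf = require(STUDY_DIR / "pools.vcf", "analysis/01_simulate.py")
    sites = read_pool_sites(vcf, format="vcf")
    mask = read_mask(STUDY_DIR / "ssr_mask.bed")
    passing, report = apply_site_filters(sites, FilterParams(), mask)

    TABLES.mkdir(parents=True, exist_ok=True)
    passing.to_csv(TABLES / "filtered_sites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(rule, n) for rule, n in report.removed.items()] + [("passing", report.n_pass)],
        columns=["rule", "count"],
    ).to_csv(TABLES / "filter_report.tsv", sep="\t", index=False)

    print(f"{report.n_input} sites in, {report.n_pass} pass")
    for rule, n in report.removed.items():
        print(f"  removed by {rule}: {n}")
    assert report.is_conserved()


if __name__ == "__main__":
    main()
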