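"""Larval phenotype differentiation: rates, one-way ANOVA, post hoc tests.

Also demonstrates the qPCR fold-change computation (2^-ΔΔCt) on example
cycle thresholds.
"""

import pandas as pd
from common import STUDY_DIR, TABLES, require

from poolscan.phenotypes import (
    compute_rates,
    pairwise_welch,
    relative_expression,
    trait_report,
)


def main() -> None:
    table = pd.read_csv(require(STUDY_DIR / "phenotypes.tsv", "analysis/01_simulate.py"), sep="\t")
    rates = compute_rates(table)
    rates.to_csv(TABLES / "phenotype_rates.tsv", sep="\t", index=False)
    report = trait_report(rates)
    report.to_csv(TABLES / "phenotype_anova.tsv", sep="\t", index=False)
    print("one-way ANOVA per trait:")
    print(report.to_string(index=False))

    posthoc = []
    for trait, sub in rates.groupby("trait"):
        ph = pairwise_welch(sub)
        ph.insert(0, "trait", trait)
        posthoc.append(ph)
    posthoc = pd.concat(posthoc, ignore_index=True)
    posthoc.to_csv(TABLES / "phenotype_posthoc.tsv", sep="\t", index=False)
    sig = posthoc.loc[posthoc["stars"] != ""]
    print(f"\npost hoc (Welch, BH-adjusted): {len(sig)} of {len(posthoc)} pairs significant")

    # example qPCR fold change: target gene 2 cycles later relative to the
    # reference in the test condition than in the control
    fold = relative_expression(24.0, 18.0, 22.0, 18.0)
    print(f"\nexample qPCR fold change (ΔΔCt = 2): 2^-ΔΔCt = {fold:.2f}")


if __name__ == "__main__":
    main()
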