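"""Integrate the AFD, F_ST and expression evidence; test term enrichment.

The candidate set is (AFD ∪ FST) ∩ DE: population-genetic differentiation
corroborated by differential expression.  Recovery of the planted sweep
genes is reported against the truth table (only sweep genes placed in the
DE list are recoverable by construction).
"""

import pandas as pd
from common import STUDY_DIR, STUDY_PARAMS, TABLES, require

from poolscan.afd import read_gene_list, write_gene_list
from poolscan.integrate import enrich_terms, venn3, venn_report
from poolscan.io import read_gene_models
from poolscan.simulate import simulate_population_frequencies


def main() -> None:
    de = read_gene_list(STUDY_DIR / "de_genes.txt")
    terms = pd.read_csv(STUDY_DIR / "gene_terms.tsv", sep="\t")
    background = sorted(g.gene_id for g in read_gene_models(STUDY_DIR / "genes.gff3"))
    truth = simulate_population_frequencies(STUDY_PARAMS)
    sweep_genes = set(truth.outlier_gene_ids)
    recoverable = sweep_genes & set(de)

    for treatment in ("hypo", "hyper"):
        afd = set(read_gene_list(require(TABLES / f"afd_genes_{treatment}.txt",
                                         "analysis/03_afd_scan.py")))
        fst = set(read_gene_list(require(TABLES / f"fst_genes_{treatment}.txt",
                                         "analysis/05_map_genes.py")))
        venn = venn3(afd, fst, de)
        venn_report(venn).to_csv(TABLES / f"venn_{treatment}.tsv", sep="\t", index=False)
        write_gene_list(venn.candidates, TABLES / f"candidates_{treatment}.txt")
        print(f"{treatment}: |AFD|={len(afd)} |FST|={len(fst)} |DE|={len(de)} "
              f"-> {len(venn.candidates)} candidates "
              f"(regions {venn.counts})")
        if treatment == STUDY_PARAMS.outlier_pool:
            got = len(venn.candidates & recoverable)
            print(f"  recoverable sweep genes recovered: {got}/{len(recoverable)} "
                  f"(of {len(sweep_genes)} planted; the rest are absent from the DE list)")

        enr = enrich_terms(venn.candidates & set(background), background, terms)
        enr.to_csv(TABLES / f"enrichment_{treatment}.tsv", sep="\t", index=False)
        sig = enr.loc[enr["p_adjusted"] < 0.05]
        print(f"  enrichment: {len(sig)} of {len(enr)} terms at adjusted p < 0.05"
              + (f"; top term {enr.loc[0, 'term']} p_adj={enr.loc[0, 'p_adjusted']:.3g}"
                 if len(enr) else ""))


if __name__ == "__main__":
    main()
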