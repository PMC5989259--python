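"""Map outlier windows to genes (± 5 kb) and classify differentiated SNP areas.

Produces the F_ST gene lists and an annotated differentiated-SNP table
with each SNP's genomic area (CDS / Intron / Intergenic) and nearest gene.
"""

import pandas as pd
from common import STUDY_DIR, STUDY_PARAMS, TABLES, require

from poolscan.afd import write_gene_list
from poolscan.fst import select_top_windows
from poolscan.genes import annotate_snp_areas, assign_snps_to_genes, genes_overlapping_windows
from poolscan.io import read_gene_models


def main() -> None:
    genes = read_gene_models(STUDY_DIR / "genes.gff3")
    for treatment in ("hypo", "hyper"):
        windows = pd.read_csv(
            require(TABLES / f"windows_{treatment}.tsv", "analysis/04_fst_scan.py"),
            sep="\t",
        )
        top = select_top_windows(windows, 0.01)
        fst_hits = genes_overlapping_windows(
            top, genes, flank_bp=5000, scaffold_lengths=STUDY_PARAMS.scaffold_lengths
        )
        write_gene_list(fst_hits, TABLES / f"fst_genes_{treatment}.txt")

        afd = pd.read_csv(
            require(TABLES / f"afd_{treatment}.tsv", "analysis/03_afd_scan.py"), sep="\t"
        )
        diff = afd.loc[afd["passes"]].copy()
        annotated = annotate_snp_areas(diff, genes)
        annotated = assign_snps_to_genes(annotated, genes, mode="nearest")
        annotated.to_csv(TABLES / f"differentiated_snps_{treatment}.tsv", sep="\t", index=False)
        areas = annotated["area"].value_counts().to_dict()
        print(f"{treatment}: {len(fst_hits)} genes near top windows; "
              f"{len(annotated)} differentiated SNPs by area {areas}")


if __name__ == "__main__":
    main()
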