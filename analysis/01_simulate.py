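"""Generate the synthetic pooled study and report what was planted.

Writes the study artifacts (pooled counts, gene models, SSR mask, term
map, DE list, phenotype table, truth tables) under results/study/.
"""

from common import STUDY_DIR, STUDY_PARAMS

from poolscan.simulate import simulate_population_frequencies, write_study


def main() -> None:
    paths = write_study(STUDY_PARAMS, STUDY_DIR)
    truth = simulate_population_frequencies(STUDY_PARAMS)
    out = truth.loci["is_outlier"].sum()
    print(f"study written to {STUDY_DIR}")
    print(f"  {len(truth.loci)} SNPs on {STUDY_PARAMS.n_scaffolds} scaffolds "
          f"({STUDY_PARAMS.scaffold_length:,} bp each)")
    print(f"  {out} planted sweep loci in {STUDY_PARAMS.n_outlier_regions} genic blocks; "
          f"sweep genes: {', '.join(truth.outlier_gene_ids)}")
    print(f"  background divergence F = {STUDY_PARAMS.background_divergence}, "
          f"sweep divergence F_out = {STUDY_PARAMS.outlier_divergence}")
    de = paths["de_list"].read_text().split()
    print(f"  DE list: {len(de)} genes "
          f"({sum(g in set(truth.outlier_gene_ids) for g in de)} of them sweep genes)")


if __name__ == "__main__":
    main()
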