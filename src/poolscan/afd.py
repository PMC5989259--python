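"""Allele-frequency estimation and allele-frequency-difference (AFD) scan.

The AFD scan is the simpler of the two differentiation scans: per SNP, the
alternate-allele frequency is estimated in each pool directly from read
counts, and a SNP is called differentiated between two populations when
the absolute frequency difference exceeds a threshold (default 0.6,
strictly — "above 0.6").  Differentiated SNPs are then assigned to genes.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genes import assign_snps_to_genes
from .io import GeneModel


def pool_allele_frequency(ref_count, alt_count):
    """Alternate-allele frequency from pooled read counts.

    Accepts scalars or arrays; total depth must be >= 1 everywhere.
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    total = ref + alt
    if np.any(total < 1):
        raise ValueError("zero total depth: frequency undefined (site should have been filtered)")
    out = alt / total
    return float(out) if out.ndim == 0 else out


def genotype_allele_frequency(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Alternate-allele frequency from genotype counts (e.g. HRM genotyping)."""
    total = n_ref_hom + n_het + n_alt_hom
    if total < 1:
        raise ValueError("no genotyped individuals")
    if min(n_ref_hom, n_het, n_alt_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    return (2 * n_alt_hom + n_het) / (2 * total)


def scan_afd(
    sites: pd.DataFrame,
    pop_a: str,
    pop_b: str,
    threshold: float = 0.6,
) -> pd.DataFrame:
    """Per-site AFD between two pools.

    Returns a table (sorted by scaffold, position) with columns
    ``scaffold, pos, freq_a, freq_b, afd, passes`` where
    ``passes`` means ``afd > threshold`` (strict).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    for pop in (pop_a, pop_b):
        if f"{pop}.ref" not in sites.columns:
            raise KeyError(f"pool {pop!r} absent from site table")
    fa = pool_allele_frequency(sites[f"{pop_a}.ref"], sites[f"{pop_a}.alt"])
    fb = pool_allele_frequency(sites[f"{pop_b}.ref"], sites[f"{pop_b}.alt"])
    afd = np.abs(fa - fb)
    out = pd.DataFrame(
        {
            "scaffold": sites["scaffold"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "freq_a": fa,
            "freq_b": fb,
            "afd": afd,
            "passes": afd > threshold,
        }
    )
    return out.sort_values(["scaffold", "pos"], kind="mergesort").reset_index(drop=True)


def afd_genes(
    afd_table: pd.DataFrame,
    genes: Sequence[GeneModel],
    flank_bp: int = 0,
    mode: str = "overlap",
) -> set[str]:
    """Genes carrying a differentiated SNP.

    A gene is returned when any passing SNP falls within its span extended
    by ``flank_bp`` (all such genes, when flanks make several overlap).
    ``mode="nearest"`` instead assigns every passing SNP to its nearest
    gene on the scaffold — the convention under which intergenic SNPs
    still receive a gene label.  Use
    :func:`poolscan.genes.assign_snps_to_genes` directly for the per-SNP
    assignment table (which also shows the SNPs hitting no gene).
    """
    passing = afd_table.loc[afd_table["passes"]]
    if passing.empty:
        return set()
    if mode == "overlap":
        hits: set[str] = set()
        by_scaffold: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_scaffold.setdefault(g.scaffold, []).append(g)
        for scaf, pos in zip(passing["scaffold"].to_numpy(), passing["pos"].to_numpy()):
            for g in by_scaffold.get(scaf, ()):
                if g.start - flank_bp <= pos < g.end + flank_bp:
                    hits.add(g.gene_id)
        return hits
    assigned = assign_snps_to_genes(passing, genes, flank_bp=flank_bp, mode=mode)
    return set(assigned["gene_id"].dropna())


def read_gene_list(path) -> list[str]:
    """Plain-text gene list (one ID per line), e.g. a DE gene list."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(gene_ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(gene_ids)):
            fh.write(f"{g}\n")
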