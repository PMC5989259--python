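"""Map outlier windows and SNPs to genes; classify SNP genomic areas.

All intervals are 0-based half-open; overlap is strict intersection
(shared boundaries do not overlap).  Strand is ignored throughout: the
scan's gene assignment is strand-agnostic.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .io import GeneModel

AREAS = ("CDS", "Intron", "Intergenic")


def _check_scaffolds(
    windows: pd.DataFrame,
    genes: Sequence[GeneModel],
    scaffold_lengths: Mapping[str, int] | None,
) -> None:
    known = {g.scaffold for g in genes}
    if scaffold_lengths:
        known |= set(scaffold_lengths)
    offending = sorted(set(windows["scaffold"].unique()) - known)
    if offending:
        raise ValueError(f"window scaffolds unknown to the gene annotation: {offending}")


def genes_overlapping_windows(
    windows: pd.DataFrame,
    genes: Sequence[GeneModel],
    flank_bp: int = 5000,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> set[str]:
    """Genes intersecting any window extended by ``flank_bp`` on both sides.

    ``windows`` needs columns ``scaffold, start, end``.  The flank is
    clipped at scaffold bounds when lengths are supplied.  Scaffold names
    present in the windows but absent from the annotation raise an error
    naming the offenders.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    _check_scaffolds(windows, genes, scaffold_lengths)
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    hits: set[str] = set()
    for row in windows.itertuples(index=False):
        ws = max(0, int(row.start) - flank_bp)
        we = int(row.end) + flank_bp
        if scaffold_lengths and row.scaffold in scaffold_lengths:
            we = min(we, scaffold_lengths[row.scaffold])
        for g in by_scaffold.get(row.scaffold, ()):
            if g.start < we and g.end > ws:
                hits.add(g.gene_id)
    return hits


def classify_snp_area(scaffold: str, pos: int, genes: Sequence[GeneModel]) -> str:
    """Classify one position as CDS, Intron or Intergenic.

    CDS when the position lies in any exon of any gene; Intron when it is
    inside a gene span but in no exon; Intergenic otherwise.  CDS takes
    precedence when overlapping genes disagree.
    """
    in_gene = False
    for g in genes:
        if g.scaffold != scaffold or not (g.start <= pos < g.end):
            continue
        for s, e in g.exons:
            if s <= pos < e:
                return "CDS"
        in_gene = True
    return "Intron" if in_gene else "Intergenic"


def annotate_snp_areas(snps: pd.DataFrame, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Add an ``area`` column to a SNP table (columns ``scaffold, pos``)."""
    out = snps.copy()
    out["area"] = [
        classify_snp_area(s, int(p), genes)
        for s, p in zip(snps["scaffold"].to_numpy(), snps["pos"].to_numpy())
    ]
    return out


def assign_snps_to_genes(
    snps: pd.DataFrame,
    genes: Sequence[GeneModel],
    flank_bp: int = 0,
    mode: str = "overlap",
) -> pd.DataFrame:
    """Assign each SNP to a gene.

    ``mode="overlap"``: the first gene (by coordinate) whose flanked span
    contains the SNP, else ``NA``.  ``mode="nearest"``: the gene with the
    smallest distance to the SNP on the same scaffold (ties by gene start;
    SNPs on gene-free scaffolds stay ``NA``); this is the convention that
    lets intergenic SNPs carry a gene label.
    """
    if mode not in {"overlap", "nearest"}:
        raise ValueError(f"unknown assignment mode {mode!r}")
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for lst in by_scaffold.values():
        lst.sort(key=lambda g: g.start)
    assigned: list[str | None] = []
    for row in snps.itertuples(index=False):
        pos = int(row.pos)
        cands = by_scaffold.get(row.scaffold, [])
        best: str | None = None
        if mode == "overlap":
            for g in cands:
                if g.start - flank_bp <= pos < g.end + flank_bp:
                    best = g.gene_id
                    break
        else:
            best_d = None
            for g in cands:
                d = 0 if g.start <= pos < g.end else max(g.start - pos, pos - g.end + 1)
                if best_d is None or d < best_d:
                    best_d, best = d, g.gene_id
        assigned.append(best)
    out = snps.copy()
    out["gene_id"] = pd.array(assigned, dtype="string")
    return out
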