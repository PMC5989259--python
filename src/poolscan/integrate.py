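"""Merge the evidence streams into candidate gene sets and test term enrichment.

Three gene sets are combined: genes with a differentiated SNP (AFD), genes
overlapping top F_ST windows (FST), and differentially expressed genes
(DE).  The candidate set is (AFD ∪ FST) ∩ DE — population-genetic signal
corroborated by expression.  Term enrichment is a one-sided hypergeometric
tail over a user-supplied gene→term table, Benjamini–Hochberg adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

EVIDENCE = ("AFD", "FST", "DE")


@dataclass
class CandidateGeneSet:
    """A named gene set with per-gene evidence provenance."""

    label: str
    genes: set[str]
    provenance: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes:
            if not self.provenance.get(g):
                raise ValueError(f"gene {g} has empty provenance")


def merge_differentiated(
    afd_genes: Iterable[str],
    fst_genes: Iterable[str],
    label: str = "differentiated",
) -> CandidateGeneSet:
    """Union of the AFD- and F_ST-derived gene sets, provenance per gene."""
    a, f = set(afd_genes), set(fst_genes)
    prov = {
        g: frozenset(tag for tag, s in (("AFD", a), ("FST", f)) if g in s)
        for g in a | f
    }
    return CandidateGeneSet(label=label, genes=a | f, provenance=prov)


@dataclass
class VennResult:
    """The seven disjoint regions of a three-set Venn partition.

    Region keys are membership strings in (AFD, FST, DE) order:
    ``"101"`` = in AFD and DE but not FST.  ``candidates`` is
    (AFD ∪ FST) ∩ DE, the expression-corroborated differentiated genes.
    """

    regions: dict[str, set[str]]
    candidates: set[str]

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def triple(self) -> set[str]:
        return self.regions["111"]


def venn3(
    afd_genes: Iterable[str],
    fst_genes: Iterable[str],
    de_genes: Iterable[str],
) -> VennResult:
    """Disjoint region memberships of the three evidence sets."""
    sets = (set(afd_genes), set(fst_genes), set(de_genes))
    universe = sets[0] | sets[1] | sets[2]
    regions: dict[str, set[str]] = {
        "".join(bits): set()
        for bits in ("100", "010", "001", "110", "101", "011", "111")
    }
    for g in universe:
        key = "".join("1" if g in s else "0" for s in sets)
        regions[key].add(g)
    candidates = (sets[0] | sets[1]) & sets[2]
    return VennResult(regions=regions, candidates=candidates)


def enrich_terms(
    candidates: Iterable[str],
    background: Iterable[str],
    gene_terms: pd.DataFrame,
) -> pd.DataFrame:
    """Hypergeometric term over-representation of a candidate gene set.

    ``gene_terms`` has columns ``gene_id, term``; genes outside the
    background are ignored in term sizes.  For each term with K background
    genes, a candidate set of size n drawn from a background of size N
    with k candidates in the term scores p = P(X >= k), X ~
    Hypergeom(N, K, n); BH-adjusted across terms, sorted by adjusted p.
    """
    cand = set(candidates)
    bg = set(background)
    missing = sorted(cand - bg)
    if missing:
        raise ValueError(f"candidate genes absent from background: {missing[:5]}")
    gt = gene_terms.loc[gene_terms["gene_id"].isin(bg)]
    term_genes: Mapping[str, set[str]] = {
        t: set(sub["gene_id"]) for t, sub in gt.groupby("term")
    }
    N, n = len(bg), len(cand)
    rows = []
    for term in sorted(term_genes):
        members = term_genes[term]
        K = len(members)
        k = len(members & cand)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, K, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p_value"])
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    out = out.sort_values(["p_adjusted", "p_value", "term"], kind="mergesort").reset_index(drop=True)
    return out


def venn_report(result: VennResult) -> pd.DataFrame:
    """Delimited-friendly Venn summary: one row per region."""
    labels = {
        "100": "AFD only",
        "010": "FST only",
        "001": "DE only",
        "110": "AFD & FST",
        "101": "AFD & DE",
        "011": "FST & DE",
        "111": "AFD & FST & DE",
    }
    rows = [
        (key, labels[key], len(result.regions[key]), ";".join(sorted(result.regions[key])))
        for key in labels
    ]
    return pd.DataFrame(rows, columns=["region", "label", "count", "genes"])
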