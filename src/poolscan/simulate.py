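"""Synthetic pooled-resequencing study generator with a known truth table.

The generator emulates the design of a pooled salinity-adaptation scan in
the Pacific oyster: three pools (a hyposalinity-adapted and a
hypersalinity-adapted treatment population plus a common control), each of
``pool_size`` diploid individuals sequenced to ~``mean_depth``x, over a toy
multi-scaffold genome carrying gene models, a simple-sequence-repeat (SSR)
mask, a gene-to-term annotation, a differential-expression (DE) gene list,
and larval phenotype tables.

Population allele frequencies follow the Balding-Nichols model: around an
ancestral frequency :math:`p_0`, each population draws

.. math:: p \\sim \\mathrm{Beta}\\bigl(p_0 (1-F)/F,\\; (1-p_0)(1-F)/F\\bigr)

with divergence ``F = background_divergence`` (:math:`F = 0` degenerates to
a point mass at :math:`p_0`).  Planted outlier loci model completed
selective sweeps in one designated treatment population: its frequency is
drawn from the same beta family around the *swept* value :math:`1 - p_0`
with divergence ``outlier_divergence``, and the whole locus is
rejection-resampled until the true contrast against the control population
is at least ``min_outlier_afd``.  Outlier loci are clustered into
``n_outlier_regions`` sweep blocks, each a single window-length tile lying
inside a gene and outside the SSR mask, emulating the footprint of linked
selection around a swept site.

Sequencing is two-stage: a pool of ``2 * pool_size`` chromosomes is sampled
from the population frequency, then reads are drawn binomially from the
pool at a truncated-Poisson depth — pooled reads carry the extra variance
of resampling a finite pool.

Every output is a deterministic function of ``SimParams`` (including its
seed); each artifact draws from its own named substream so any single
output can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    GeneModel,
    write_gene_models,
    write_mask,
    write_pool_sites,
    write_vcf,
)

POOLS = ("hypo", "hyper", "control")
TRAITS = ("production", "survival", "growth", "adhesive")

#: named substreams, so each artifact is reproducible in isolation
_STREAMS = ("layout", "mask", "terms", "de", "freqs", "reads", "quality", "phenotypes")


class ParamError(ValueError):
    """Simulation parameters violate their invariants."""


@dataclass(frozen=True)
class SimParams:
    """Conditions of a synthetic pooled-resequencing study.

    Defaults describe the emulated study: 46 diploid individuals per pool,
    ~35x mean depth, a 1-Mb genome of ten 100-kb scaffolds tiled into
    1,000 analysis windows, weak background divergence (F = 0.05) and 50
    swept outlier loci (F_out = 0.6) clustered in 5 genic sweep blocks.
    """

    n_scaffolds: int = 10
    scaffold_length: int = 100_000
    n_snps: int = 5_000
    pool_size: int = 46
    mean_depth: float = 35.0
    background_divergence: float = 0.05
    n_outlier_loci: int = 50
    outlier_divergence: float = 0.6
    n_outlier_regions: int = 5
    min_outlier_afd: float = 0.8
    outlier_pool: str = "hypo"
    sweep_tile_bp: int = 1_000
    ssr_fraction: float = 0.05
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (2_000, 4_000)
    gene_flank_bp: int = 5_000
    n_terms: int = 25
    de_overlap_fraction: float = 0.5
    de_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_scaffolds": self.n_scaffolds,
            "scaffold_length": self.scaffold_length,
            "n_snps": self.n_snps,
            "pool_size": self.pool_size,
            "n_genes": self.n_genes,
            "n_terms": self.n_terms,
            "sweep_tile_bp": self.sweep_tile_bp,
        }
        for name, v in counts.items():
            if v < 1:
                raise ParamError(f"{name} must be positive (got {v})")
        if self.mean_depth <= 0:
            raise ParamError("mean_depth must be positive")
        if not 0 <= self.background_divergence < 1:
            raise ParamError("background_divergence must lie in [0, 1)")
        if self.n_outlier_loci < 0 or self.n_outlier_loci > self.n_snps:
            raise ParamError("need 0 <= n_outlier_loci <= n_snps")
        if self.n_outlier_loci > 0:
            if not self.background_divergence < self.outlier_divergence < 1:
                raise ParamError(
                    "need background_divergence < outlier_divergence < 1"
                )
            if self.n_outlier_regions < 1 or self.n_outlier_regions > self.n_outlier_loci:
                raise ParamError("need 1 <= n_outlier_regions <= n_outlier_loci")
        if not 0 < self.min_outlier_afd < 1:
            raise ParamError("min_outlier_afd must lie in (0, 1)")
        if self.outlier_pool not in POOLS:
            raise ParamError(f"outlier_pool must be one of {POOLS}")
        for name, frac in (
            ("ssr_fraction", self.ssr_fraction),
            ("de_fraction", self.de_fraction),
        ):
            if not 0 <= frac < 1:
                raise ParamError(f"{name} must lie in [0, 1)")
        if not 0 <= self.de_overlap_fraction <= 1:
            raise ParamError("de_overlap_fraction must lie in [0, 1]")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ParamError("gene_length_range must be 0 < lo <= hi")
        if hi > self.scaffold_length:
            raise ParamError("genes longer than scaffolds cannot be placed")

    @property
    def scaffold_names(self) -> list[str]:
        return [f"scaffold{i + 1}" for i in range(self.n_scaffolds)]

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {s: self.scaffold_length for s in self.scaffold_names}


@dataclass
class Annotation:
    """Gene models, SSR mask, term map and DE list for one simulated study."""

    genes: list[GeneModel]
    mask: dict[str, list[tuple[int, int]]]
    terms: pd.DataFrame  # columns: gene_id, term
    de_genes: list[str]


@dataclass
class SimTruth:
    """Ground truth of a simulated study: the acceptance oracle.

    ``loci`` has one row per SNP with the ancestral and true per-population
    frequencies and the outlier flag; ``genes`` has one row per gene with
    ``contains_outlier`` and ``is_de`` flags.
    """

    loci: pd.DataFrame
    genes: pd.DataFrame
    params: SimParams = field(repr=False)

    @property
    def outlier_gene_ids(self) -> list[str]:
        return self.genes.loc[self.genes["contains_outlier"], "gene_id"].tolist()


def _rng(params: SimParams, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(_STREAMS.index(stream),))
    )


def balding_nichols(
    p0: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw population frequencies around ancestral ``p0`` at divergence ``F``."""
    p0 = np.asarray(p0, dtype=float)
    if F == 0:
        return p0.copy()
    scale = (1.0 - F) / F
    return rng.beta(p0 * scale, (1.0 - p0) * scale)


# ---------------------------------------------------------------------------
# layout: genes, mask, sweep blocks (shared by several outputs)
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    genes: list[GeneModel]
    mask: dict[str, list[tuple[int, int]]]
    sweep_blocks: list[tuple[str, int, int, str]]  # scaffold, start, end, gene_id


def _place_genes(params: SimParams, rng: np.random.Generator) -> list[GeneModel]:
    lo, hi = params.gene_length_range
    names = params.scaffold_names
    per_scaffold = [params.n_genes // params.n_scaffolds] * params.n_scaffolds
    for i in range(params.n_genes % params.n_scaffolds):
        per_scaffold[i] += 1
    genes: list[GeneModel] = []
    gid = 0
    for scaf, g in zip(names, per_scaffold):
        if g == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=g)
        free = params.scaffold_length - int(lengths.sum())
        if free < g + 1:
            raise ParamError(
                f"cannot place {g} non-overlapping genes of ~{hi} bp on a "
                f"{params.scaffold_length}-bp scaffold"
            )
        gaps = rng.multinomial(free, np.full(g + 1, 1.0 / (g + 1)))
        pos = 0
        for k in range(g):
            pos += int(gaps[k])
            start, end = pos, pos + int(lengths[k])
            genes.append(_make_gene(f"GENE{gid + 1:05d}", scaf, start, end, rng))
            gid += 1
            pos = end
    return genes


def _make_gene(
    gene_id: str, scaffold: str, start: int, end: int, rng: np.random.Generator
) -> GeneModel:
    span = end - start
    n_exons = int(rng.integers(2, 5))
    n_chunks = 2 * n_exons - 1  # exon, intron, exon, ...
    min_w = 50
    extra = span - min_w * n_chunks
    if extra < 0:  # short gene: single exon
        return GeneModel(gene_id, scaffold, "+" if rng.random() < 0.5 else "-",
                         start, end, ((start, end),))
    widths = rng.multinomial(extra, np.full(n_chunks, 1.0 / n_chunks)) + min_w
    edges = start + np.concatenate([[0], np.cumsum(widths)])
    exons = tuple((int(edges[i]), int(edges[i + 1])) for i in range(0, n_chunks, 2))
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gene_id, scaffold, strand, start, end, exons)


def _place_mask(params: SimParams, rng: np.random.Generator) -> dict[str, list[tuple[int, int]]]:
    mask: dict[str, list[tuple[int, int]]] = {s: [] for s in params.scaffold_names}
    target = params.ssr_fraction * params.n_scaffolds * params.scaffold_length
    covered = 0
    while covered < target:
        scaf = params.scaffold_names[int(rng.integers(params.n_scaffolds))]
        length = int(rng.integers(100, 501))
        start = int(rng.integers(0, params.scaffold_length - length))
        mask[scaf].append((start, start + length))
        covered += length
    merged: dict[str, list[tuple[int, int]]] = {}
    for scaf, ivs in mask.items():
        out: list[tuple[int, int]] = []
        for s, e in sorted(ivs):
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        if out:
            merged[scaf] = out
    return merged


def _tile_in_mask(scaf: str, start: int, end: int, mask: Mapping[str, list[tuple[int, int]]]) -> bool:
    for s, e in mask.get(scaf, ()):
        if s < end and e > start:
            return True
    return False


def _layout(params: SimParams) -> _Layout:
    genes = _place_genes(params, _rng(params, "layout"))
    mask = _place_mask(params, _rng(params, "mask"))
    # sweep-block choice draws from its own stream so it stays independent
    # of gene-placement internals
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(len(_STREAMS),))
    )
    blocks: list[tuple[str, int, int, str]] = []
    if params.n_outlier_loci > 0:
        tile = params.sweep_tile_bp
        candidates: list[tuple[str, int, int, str]] = []
        for g in genes:
            first = ((g.start + tile - 1) // tile) * tile
            for t0 in range(first, g.end - tile + 1, tile):
                if not _tile_in_mask(g.scaffold, t0, t0 + tile, mask):
                    candidates.append((g.scaffold, t0, t0 + tile, g.gene_id))
        # at most one block per gene, for distinct sweep targets
        by_gene: dict[str, list[tuple[str, int, int, str]]] = {}
        for c in candidates:
            by_gene.setdefault(c[3], []).append(c)
        gene_ids = sorted(by_gene)
        if len(gene_ids) < params.n_outlier_regions:
            raise ParamError(
                f"only {len(gene_ids)} genes can host a sweep block; "
                f"{params.n_outlier_regions} requested"
            )
        chosen_genes = rng.choice(len(gene_ids), size=params.n_outlier_regions, replace=False)
        for gi in sorted(chosen_genes):
            opts = by_gene[gene_ids[gi]]
            blocks.append(opts[int(rng.integers(len(opts)))])
        blocks.sort()
    return _Layout(genes=genes, mask=mask, sweep_blocks=blocks)


# ---------------------------------------------------------------------------
# frequencies and truth
# ---------------------------------------------------------------------------

def simulate_population_frequencies(params: SimParams) -> SimTruth:
    """Draw true per-population allele frequencies and build the truth table.

    Background loci: ancestral frequency ~ U(0.05, 0.95), every population
    an independent Balding-Nichols draw at ``background_divergence``.
    Outlier loci: ancestral frequency ~ U(0.05, 0.15); the designated
    treatment population is swept (Balding-Nichols around ``1 - p0`` at
    ``outlier_divergence``), the locus rejection-resampled until the true
    contrast with the control reaches ``min_outlier_afd``.
    """
    params.validate()
    layout = _layout(params)
    rng = _rng(params, "freqs")

    # --- positions -------------------------------------------------------
    n_out = params.n_outlier_loci
    n_bg = params.n_snps - n_out
    out_pos: list[tuple[str, int]] = []
    if n_out:
        per_block = np.full(len(layout.sweep_blocks), n_out // len(layout.sweep_blocks))
        per_block[: n_out % len(layout.sweep_blocks)] += 1
        for (scaf, b0, b1, _gid), k in zip(layout.sweep_blocks, per_block):
            pos = rng.choice(np.arange(b0, b1), size=int(k), replace=False)
            out_pos.extend((scaf, int(p)) for p in pos)

    blocked = {
        scaf: [(b0, b1) for s, b0, b1, _ in layout.sweep_blocks if s == scaf]
        for scaf in params.scaffold_names
    }
    per_scaffold = rng.multinomial(n_bg, np.full(params.n_scaffolds, 1 / params.n_scaffolds))
    bg_pos: list[tuple[str, int]] = []
    for scaf, k in zip(params.scaffold_names, per_scaffold):
        allowed = np.ones(params.scaffold_length, dtype=bool)
        for b0, b1 in blocked[scaf]:
            allowed[b0:b1] = False
        pool = np.flatnonzero(allowed)
        pos = rng.choice(pool, size=int(k), replace=False)
        bg_pos.extend((scaf, int(p)) for p in pos)

    scaffolds = np.array([s for s, _ in out_pos] + [s for s, _ in bg_pos])
    positions = np.array([p for _, p in out_pos] + [p for _, p in bg_pos])
    is_outlier = np.zeros(params.n_snps, dtype=bool)
    is_outlier[:n_out] = True

    # --- frequencies -----------------------------------------------------
    F = params.background_divergence
    Fo = params.outlier_divergence
    p0 = np.empty(params.n_snps)
    freqs = {pool: np.empty(params.n_snps) for pool in POOLS}

    p0[n_out:] = rng.uniform(0.05, 0.95, n_bg)
    for pool in POOLS:
        freqs[pool][n_out:] = balding_nichols(p0[n_out:], F, rng)

    if n_out:
        todo = np.ones(n_out, dtype=bool)
        guard = 0
        while todo.any():
            m = int(todo.sum())
            p0[:n_out][todo] = rng.uniform(0.05, 0.15, m)
            for pool in POOLS:
                if pool == params.outlier_pool:
                    freqs[pool][:n_out][todo] = balding_nichols(
                        1.0 - p0[:n_out][todo], Fo, rng
                    )
                else:
                    freqs[pool][:n_out][todo] = balding_nichols(p0[:n_out][todo], F, rng)
            contrast = np.abs(
                freqs[params.outlier_pool][:n_out] - freqs["control"][:n_out]
            )
            todo = contrast < params.min_outlier_afd
            guard += 1
            if guard > 1000:  # pragma: no cover - defensive
                raise RuntimeError("sweep rejection sampling failed to converge")

    loci = pd.DataFrame(
        {
            "scaffold": scaffolds,
            "pos": positions,
            "ancestral": p0,
            **{f"p_{pool}": freqs[pool] for pool in POOLS},
            "is_outlier": is_outlier,
        }
    )
    order = np.lexsort((loci["pos"].to_numpy(), loci["scaffold"].to_numpy()))
    loci = loci.iloc[order].reset_index(drop=True)

    genes_df = _gene_truth(params, layout)
    return SimTruth(loci=loci, genes=genes_df, params=params)


def _de_assignment(params: SimParams, layout: _Layout) -> list[str]:
    rng = _rng(params, "de")
    outlier_genes = sorted({b[3] for b in layout.sweep_blocks})
    k = int(round(params.de_overlap_fraction * len(outlier_genes)))
    de: set[str] = set()
    if k:
        idx = rng.choice(len(outlier_genes), size=k, replace=False)
        de.update(outlier_genes[i] for i in sorted(idx))
    others = sorted(g.gene_id for g in layout.genes if g.gene_id not in outlier_genes)
    k_bg = int(round(params.de_fraction * len(others)))
    if k_bg:
        idx = rng.choice(len(others), size=k_bg, replace=False)
        de.update(others[i] for i in sorted(idx))
    return sorted(de)


def _gene_truth(params: SimParams, layout: _Layout) -> pd.DataFrame:
    outlier_genes = {b[3] for b in layout.sweep_blocks}
    de = set(_de_assignment(params, layout))
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in layout.genes],
            "scaffold": [g.scaffold for g in layout.genes],
            "start": [g.start for g in layout.genes],
            "end": [g.end for g in layout.genes],
            "contains_outlier": [g.gene_id in outlier_genes for g in layout.genes],
            "is_de": [g.gene_id in de for g in layout.genes],
        }
    )


# ---------------------------------------------------------------------------
# annotation artifacts
# ---------------------------------------------------------------------------

def simulate_annotation(params: SimParams) -> Annotation:
    """Gene models, SSR mask, gene->term map and DE gene list.

    Deterministically consistent with :func:`simulate_population_frequencies`
    for the same parameters (both derive from the same layout substream).
    """
    params.validate()
    layout = _layout(params)
    rng = _rng(params, "terms")
    term_ids = [f"T{i + 1:04d}" for i in range(params.n_terms)]
    rows = []
    for i, g in enumerate(layout.genes):
        assigned = {term_ids[i % params.n_terms]}  # every term gets >= 1 gene
        extra = int(rng.integers(0, 3))
        if extra:
            assigned.update(rng.choice(term_ids, size=extra, replace=False))
        for t in sorted(assigned):
            rows.append((g.gene_id, t))
    terms = pd.DataFrame(rows, columns=["gene_id", "term"])
    return Annotation(
        genes=layout.genes,
        mask=layout.mask,
        terms=terms,
        de_genes=_de_assignment(params, layout),
    )


# ---------------------------------------------------------------------------
# pooled reads
# ---------------------------------------------------------------------------

def _truncated_poisson(mean: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1."""
    d = rng.poisson(mean, size)
    zero = d == 0
    while zero.any():
        d[zero] = rng.poisson(mean, int(zero.sum()))
        zero = d == 0
    return d


def simulate_pool_reads(truth: SimTruth, params: SimParams | None = None) -> pd.DataFrame:
    """Sample pooled read counts for every locus and pool.

    Two-stage sampling: ``2 * pool_size`` chromosomes are drawn binomially
    from the true population frequency, then reads are drawn binomially
    from the realised pool frequency at a truncated-Poisson depth.
    Returns a site table in the internal representation (see ``io``),
    with SSR-mask membership in ``in_ssr`` and base qualities ~ N(36, 3)
    clipped to [2, 41].
    """
    if params is None:
        params = truth.params
    loci = truth.loci
    if ((loci[[f"p_{p}" for p in POOLS]] < 0) | (loci[[f"p_{p}" for p in POOLS]] > 1)).any().any():
        raise ParamError("truth frequencies must lie in [0, 1]")
    n = len(loci)
    rng = _rng(params, "reads")
    qrng = _rng(params, "quality")

    ref_base = rng.choice(list("ATCG"), size=n)
    alt_base = np.empty(n, dtype="<U1")
    for i, rb in enumerate(ref_base):
        others = [b for b in "ATCG" if b != rb]
        alt_base[i] = others[int(rng.integers(3))]

    data = {
        "scaffold": loci["scaffold"].to_numpy(),
        "pos": loci["pos"].to_numpy(),
        "ref": ref_base,
        "alt": alt_base,
        "base_quality": np.clip(np.round(qrng.normal(36, 3, n)), 2, 41),
    }
    two_n = 2 * params.pool_size
    for pool in POOLS:
        p_true = loci[f"p_{pool}"].to_numpy()
        depth = _truncated_poisson(params.mean_depth, n, rng)
        k = rng.binomial(two_n, p_true)
        alt_reads = rng.binomial(depth, k / two_n)
        data[f"{pool}.ref"] = depth - alt_reads
        data[f"{pool}.alt"] = alt_reads
    sites = pd.DataFrame(data)

    layout = _layout(params)
    in_ssr = np.zeros(n, dtype=bool)
    for i, (scaf, pos) in enumerate(zip(sites["scaffold"], sites["pos"])):
        for s, e in layout.mask.get(scaf, ()):
            if s <= pos < e:
                in_ssr[i] = True
                break
    sites["in_ssr"] = in_ssr
    return sites


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

#: plausible larval rates for the three groups (control vs adapted lines);
#: synthetic conditions, not measurements
DEFAULT_PHENOTYPE_MEANS: dict[str, dict[str, float]] = {
    "production": {"hypo": 0.62, "hyper": 0.58, "control": 0.50},
    "survival": {"hypo": 0.52, "hyper": 0.48, "control": 0.40},
    "growth": {"hypo": 0.38, "hyper": 0.35, "control": 0.30},
    "adhesive": {"hypo": 0.45, "hyper": 0.42, "control": 0.35},
}
DEFAULT_PHENOTYPE_SDS: dict[str, dict[str, float]] = {
    t: {g: 0.04 for g in POOLS} for t in TRAITS
}
#: per-replicate starting counts (eggs; D-larvae; eye-spot larvae)
_TRAIT_DENOMINATORS = {"production": 400, "survival": 300, "adhesive": 200}


def simulate_phenotypes(
    group_means: Mapping[str, Mapping[str, float]] | None = None,
    group_sds: Mapping[str, Mapping[str, float]] | None = None,
    n_per_group: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate-level larval phenotype counts for the four traits.

    Count traits (production, survival, adhesive) store a numerator count
    drawn binomially at a per-replicate rate jittered around the group
    mean; growth stores mean shell heights (denominator = before,
    numerator = after).  Rates recomputed downstream recover the intended
    group means up to sampling error.
    """
    means = {t: dict(DEFAULT_PHENOTYPE_MEANS[t]) for t in TRAITS}
    sds = {t: dict(DEFAULT_PHENOTYPE_SDS[t]) for t in TRAITS}
    if group_means:
        for t, by_group in group_means.items():
            means.setdefault(t, {}).update(by_group)
    if group_sds:
        for t, by_group in group_sds.items():
            sds.setdefault(t, {}).update(by_group)
    if n_per_group < 1:
        raise ParamError("n_per_group must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(999,)))
    rows = []
    for trait in means:
        for group in means[trait]:
            mu, sd = means[trait][group], sds[trait][group]
            for rep in range(1, n_per_group + 1):
                rate = float(np.clip(rng.normal(mu, sd), 0.0, 1.0))
                if trait == "growth":
                    before = float(np.round(rng.normal(70.0, 2.0), 2))
                    after = float(np.round(before * (1.0 + rate), 2))
                    rows.append((trait, group, rep, after, before))
                else:
                    denom = _TRAIT_DENOMINATORS[trait]
                    num = int(rng.binomial(denom, rate))
                    rows.append((trait, group, rep, num, denom))
    return pd.DataFrame(rows, columns=["trait", "group", "replicate", "numerator", "denominator"])


# ---------------------------------------------------------------------------
# file surface
# ---------------------------------------------------------------------------

def write_study(
    params: SimParams,
    outdir: str | Path,
    formats: Sequence[str] = ("sync", "vcf"),
) -> dict[str, Path]:
    """Generate a complete study on disk; returns the artifact paths.

    Writes pooled counts (sync and/or VCF), GFF3 gene models, BED SSR
    mask, gene->term table, DE gene list, truth tables and phenotype
    table.  Byte-identical for identical parameters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_population_frequencies(params)
    ann = simulate_annotation(params)
    sites = simulate_pool_reads(truth, params)

    paths: dict[str, Path] = {}
    site_cols = [c for c in sites.columns if c != "in_ssr"]
    if "sync" in formats:
        paths["sync"] = write_pool_sites(sites[site_cols], outdir / "pools.sync")
    if "vcf" in formats:
        paths["vcf"] = write_vcf(sites[site_cols], outdir / "pools.vcf", params.scaffold_lengths)
    paths["gff"] = write_gene_models(ann.genes, outdir / "genes.gff3")
    paths["mask"] = write_mask(ann.mask, outdir / "ssr_mask.bed")

    paths["terms"] = outdir / "gene_terms.tsv"
    ann.terms.to_csv(paths["terms"], sep="\t", index=False)
    paths["de_list"] = outdir / "de_genes.txt"
    paths["de_list"].write_text("".join(f"{g}\n" for g in ann.de_genes))

    paths["truth_loci"] = outdir / "truth_loci.tsv"
    truth.loci.to_csv(paths["truth_loci"], sep="\t", index=False, float_format="%.8g")
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)

    pheno = simulate_phenotypes(seed=params.seed)
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False)
    paths["scaffolds"] = outdir / "scaffolds.tsv"
    with open(paths["scaffolds"], "w") as fh:
        for name, length in params.scaffold_lengths.items():
            fh.write(f"{name}\t{length}\n")
    return paths


def load_truth(outdir: str | Path, params: SimParams) -> SimTruth:
    """Reload a written truth table."""
    outdir = Path(outdir)
    loci = pd.read_csv(outdir / "truth_loci.tsv", sep="\t")
    genes = pd.read_csv(outdir / "truth_genes.tsv", sep="\t")
    return SimTruth(loci=loci, genes=genes, params=params)
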