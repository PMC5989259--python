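"""Read/write pooled variant tables, gene models and masks; site-level SNP filtering.

Internal conventions
--------------------
* Coordinates are 0-based half-open everywhere inside the package.
  Conversion happens exactly once, at the file boundary: sync and VCF
  positions (1-based) and GFF3 intervals (1-based inclusive) are converted
  on read and back-converted on write; BED is consumed natively.
* A site table is a :class:`pandas.DataFrame` with columns
  ``scaffold, pos, ref, alt, base_quality`` plus, for every pool *P*,
  ``P.ref`` and ``P.alt`` read counts.  Pool names are recovered with
  :func:`pool_names`.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

BASES = ("A", "T", "C", "G")
#: order of the count fields in a sync column
SYNC_ORDER = ("A", "T", "C", "G", "N", "del")

SITE_COLUMNS = ["scaffold", "pos", "ref", "alt", "base_quality"]

#: fixed evaluation order of the site filters (first failing rule is the
#: one attributed in the report)
FILTER_RULES = ("min_depth", "het_depth", "max_depth", "base_quality", "ssr")


class MalformedInputError(ValueError):
    """An input file does not parse in its declared dialect."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure, in 0-based half-open coordinates."""

    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid span for {self.gene_id}: [{self.start}, {self.end})")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon [{s}, {e}) outside gene span of {self.gene_id}")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intervals between consecutive exons."""
        ex = sorted(self.exons)
        return tuple((a[1], b[0]) for a, b in zip(ex, ex[1:]) if b[0] > a[1])


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the site filter.

    Defaults implement the scan's standard rules: per-pool depth >= 2
    (>= 3 where the pool shows both alleles), depth <= 3x the pool's mean,
    base quality > 20, and exclusion of simple-sequence-repeat regions.
    """

    min_depth: int = 2
    min_depth_het: int = 3
    max_depth_factor: float = 3.0
    min_base_quality: float = 20.0
    exclude_ssr: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.min_depth_het < self.min_depth:
            raise ValueError("min_depth_het must be >= min_depth")
        if not self.max_depth_factor > 1:
            raise ValueError("max_depth_factor must be > 1")


@dataclass
class FilterReport:
    """Accounting of the site filter: input = passing + sum(removed)."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_pass: int = 0

    def is_conserved(self) -> bool:
        return self.n_input == self.n_pass + sum(self.removed.values())


def pool_names(sites: pd.DataFrame) -> list[str]:
    """Pool labels present in a site table (from its ``<pool>.ref`` columns)."""
    return [c[:-4] for c in sites.columns if c.endswith(".ref")]


def _depth_matrix(sites: pd.DataFrame, pools: Sequence[str]) -> np.ndarray:
    return np.column_stack(
        [sites[f"{p}.ref"].to_numpy() + sites[f"{p}.alt"].to_numpy() for p in pools]
    )


# ---------------------------------------------------------------------------
# sync dialect
# ---------------------------------------------------------------------------

def read_pool_sites(
    path: str | Path,
    format: str | None = None,
    pools: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a pooled site table from a sync or VCF file.

    Sites are normalised to biallelic records: the most frequent
    non-reference base summed across pools becomes the alternate allele;
    sites with reads on more than one non-reference base are dropped and
    counted (``df.attrs["n_multiallelic"]``), as are sites with no
    alternate reads at all (``df.attrs["n_monomorphic"]``).

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"sync"`` or ``"vcf"``; inferred from the extension when omitted.
    pools:
        Pool labels for the sync columns (defaults to ``pool1..poolK``);
        ignored for VCF, where sample names are used.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".bcf"} or path.name.endswith(".vcf.gz") else "sync"
    if format == "sync":
        return _read_sync(path, pools)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_sync(path: Path, pools: Sequence[str] | None) -> pd.DataFrame:
    rows: list[list] = []
    n_multi = 0
    n_mono = 0
    n_pools: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise MalformedInputError(f"{path}:{lineno}: expected >= 4 tab-separated fields")
            scaffold, pos_s, ref = fields[0], fields[1], fields[2].upper()
            try:
                pos1 = int(pos_s)
            except ValueError as exc:
                raise MalformedInputError(f"{path}:{lineno}: bad position {pos_s!r}") from exc
            if pos1 < 1:
                raise MalformedInputError(f"{path}:{lineno}: position must be >= 1")
            counts = []
            for col in fields[3:]:
                parts = col.split(":")
                if len(parts) != 6:
                    raise MalformedInputError(
                        f"{path}:{lineno}: pool column {col!r} is not A:T:C:G:N:del"
                    )
                try:
                    counts.append([int(x) for x in parts])
                except ValueError as exc:
                    raise MalformedInputError(f"{path}:{lineno}: non-integer count in {col!r}") from exc
            if n_pools is None:
                n_pools = len(counts)
            elif len(counts) != n_pools:
                raise MalformedInputError(f"{path}:{lineno}: inconsistent pool column count")
            arr = np.asarray(counts)  # pools x 6
            totals = arr[:, :4].sum(axis=0)
            nonref = [b for i, b in enumerate(BASES) if b != ref and totals[i] > 0]
            if len(nonref) > 1:
                n_multi += 1
                continue
            if not nonref:
                n_mono += 1
                continue
            alt = nonref[0]
            iref, ialt = BASES.index(ref), BASES.index(alt)
            row = [scaffold, pos1 - 1, ref, alt, np.nan]
            for p in range(arr.shape[0]):
                row.extend([arr[p, iref], arr[p, ialt]])
            rows.append(row)
    if n_pools is None:
        n_pools = 0
    labels = list(pools) if pools is not None else [f"pool{i + 1}" for i in range(n_pools)]
    if pools is not None and len(labels) != n_pools:
        raise ValueError(f"{len(labels)} pool names given for {n_pools} sync columns")
    cols = SITE_COLUMNS + [f"{p}.{k}" for p in labels for k in ("ref", "alt")]
    df = pd.DataFrame(rows, columns=cols)
    df = df.astype({"pos": np.int64, **{c: np.int64 for c in cols[5:]}})
    df.attrs["n_multiallelic"] = n_multi
    df.attrs["n_monomorphic"] = n_mono
    if n_multi:
        log.info("dropped %d multi-allelic sites from %s", n_multi, path)
    return df


def write_pool_sites(sites: pd.DataFrame, path: str | Path) -> Path:
    """Write a site table in the sync dialect (1-based positions).

    Base qualities are not representable in sync and are dropped.
    """
    path = Path(path)
    pools = pool_names(sites)
    records = sites.to_dict("records")
    with open(path, "w") as fh:
        for d in records:
            cols = [d["scaffold"], str(int(d["pos"]) + 1), d["ref"]]
            for p in pools:
                counts = dict.fromkeys(SYNC_ORDER, 0)
                counts[d["ref"]] = int(d[f"{p}.ref"])
                counts[d["alt"]] = int(d[f"{p}.alt"])
                cols.append(":".join(str(counts[b]) for b in SYNC_ORDER))
            fh.write("\t".join(cols) + "\n")
    return path


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _read_vcf(path: Path) -> pd.DataFrame:
    n_multi = 0
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            qual = float(rec.qual) if rec.qual is not None else np.nan
            row = [rec.chrom, rec.pos - 1, rec.ref, rec.alts[0], qual]
            ok = True
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or len(ad) != 2:
                    ok = False
                    break
                row.extend([int(ad[0]), int(ad[1])])
            if ok:
                rows.append(row)
    cols = SITE_COLUMNS + [f"{s}.{k}" for s in samples for k in ("ref", "alt")]
    df = pd.DataFrame(rows, columns=cols)
    df = df.astype({"pos": np.int64, **{c: np.int64 for c in cols[5:]}})
    df.attrs["n_multiallelic"] = n_multi
    df.attrs["n_monomorphic"] = 0
    return df


def write_vcf(
    sites: pd.DataFrame,
    path: str | Path,
    scaffold_lengths: Mapping[str, int],
) -> Path:
    """Write a site table as an uncompressed VCF with per-pool AD fields."""
    path = Path(path)
    pools = pool_names(sites)
    header = pysam.VariantHeader()
    for name, length in scaffold_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", "1", "Integer", "Read depth")
    for p in pools:
        header.add_sample(p)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for d in sites.sort_values(["scaffold", "pos"], kind="mergesort").to_dict("records"):
            rec = out.new_record(
                contig=d["scaffold"],
                start=int(d["pos"]),
                stop=int(d["pos"]) + 1,
                alleles=(d["ref"], d["alt"]),
            )
            bq = d["base_quality"]
            rec.qual = None if pd.isna(bq) else float(bq)
            for p in pools:
                r, a = int(d[f"{p}.ref"]), int(d[f"{p}.alt"])
                rec.samples[p]["AD"] = (r, a)
                rec.samples[p]["DP"] = r + a
            out.write(rec)
    return path


# ---------------------------------------------------------------------------
# masks and gene models
# ---------------------------------------------------------------------------

def read_mask(bed_path: str | Path) -> dict[str, IntervalTree]:
    """Read a BED mask into per-scaffold interval trees (0-based half-open)."""
    masks: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MalformedInputError(f"{bed_path}:{lineno}: expected >= 3 BED fields")
            scaf, start, end = fields[0], int(fields[1]), int(fields[2])
            if end > start:
                masks.setdefault(scaf, IntervalTree()).addi(start, end)
    return masks


def write_mask(intervals: Mapping[str, Iterable[tuple[int, int]]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for scaf in sorted(intervals):
            for start, end in sorted(intervals[scaf]):
                fh.write(f"{scaf}\t{start}\t{end}\n")
    return path


def mask_membership(sites: pd.DataFrame, mask: Mapping[str, IntervalTree] | None) -> np.ndarray:
    """Boolean array: is each site inside the mask?"""
    flags = np.zeros(len(sites), dtype=bool)
    if not mask:
        return flags
    known = set(sites["scaffold"].unique())
    for scaf in mask:
        if scaf not in known:
            warnings.warn(f"mask scaffold {scaf!r} absent from site table; ignored", stacklevel=2)
    for i, (scaf, pos) in enumerate(zip(sites["scaffold"].to_numpy(), sites["pos"].to_numpy())):
        tree = mask.get(scaf)
        if tree is not None and tree.overlaps_point(int(pos)):
            flags[i] = True
    return flags


def read_gene_models(
    gff_path: str | Path,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Load gene models (with exons) from GFF3.

    GFF3's 1-based inclusive intervals are converted to the internal
    0-based half-open convention here, and nowhere else.
    """
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        exons = tuple(
            sorted((ex.start - 1, ex.end) for ex in db.children(feat, featuretype="exon"))
        )
        gid = feat.attributes.get("ID", [feat.id])[0]
        gene = GeneModel(
            gene_id=gid,
            scaffold=feat.seqid,
            strand=feat.strand or ".",
            start=feat.start - 1,
            end=feat.end,
            exons=exons,
        )
        if scaffold_lengths is not None:
            L = scaffold_lengths.get(gene.scaffold)
            if L is not None and gene.end > L:
                warnings.warn(f"gene {gid} extends past the end of {gene.scaffold}", stacklevel=2)
        genes.append(gene)
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> Path:
    """Write gene models as GFF3 (converting back to 1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold, g.start)):
            fh.write(
                f"{g.scaffold}\tpoolscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), 1):
                fh.write(
                    f"{g.scaffold}\tpoolscan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
    return path


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def apply_site_filters(
    sites: pd.DataFrame,
    params: FilterParams | None = None,
    mask: Mapping[str, IntervalTree] | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the site filters and account for every removal.

    A site passes iff, in **every** pool, depth >= ``min_depth`` (and
    >= ``min_depth_het`` where the pool shows reads on both alleles),
    depth <= ``max_depth_factor`` x that pool's mean depth over the input
    table, the site's base quality >= ``min_base_quality`` (missing
    qualities pass), and the site lies outside the SSR mask.

    Rules are evaluated in the fixed order :data:`FILTER_RULES`; a removed
    site is attributed to the first rule it fails, so the report's per-rule
    counts plus the passing count always equal the input count.
    """
    if params is None:
        params = FilterParams()
    if len(sites) == 0:
        raise ValueError("cannot filter an empty site table")
    pools = pool_names(sites)
    if not pools:
        raise ValueError("site table has no pool columns")
    depth = _depth_matrix(sites, pools)
    ref = np.column_stack([sites[f"{p}.ref"].to_numpy() for p in pools])
    alt = np.column_stack([sites[f"{p}.alt"].to_numpy() for p in pools])

    mean_depth = depth.mean(axis=0)  # per pool, over pre-filter sites

    fail = {}
    fail["min_depth"] = (depth < params.min_depth).any(axis=1)
    het = (ref > 0) & (alt > 0)
    fail["het_depth"] = (het & (depth < params.min_depth_het)).any(axis=1)
    fail["max_depth"] = (depth > params.max_depth_factor * mean_depth[None, :]).any(axis=1)
    bq = sites["base_quality"].to_numpy(dtype=float)
    fail["base_quality"] = ~np.isnan(bq) & (bq < params.min_base_quality)
    if params.exclude_ssr:
        fail["ssr"] = mask_membership(sites, mask)
    else:
        fail["ssr"] = np.zeros(len(sites), dtype=bool)

    report = FilterReport(n_input=len(sites))
    attributed = np.zeros(len(sites), dtype=bool)
    for rule in FILTER_RULES:
        hit = fail[rule] & ~attributed
        report.removed[rule] = int(hit.sum())
        attributed |= fail[rule]
    passing = sites.loc[~attributed].reset_index(drop=True)
    passing.attrs = dict(sites.attrs)
    report.n_pass = len(passing)
    assert report.is_conserved()
    return passing, report


def file_sha256(path: str | Path) -> str:
    """Checksum used in run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
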