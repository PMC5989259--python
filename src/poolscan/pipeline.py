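"""Orchestrate the scan stages: filter → afd → fst → map-genes → integrate → enrich.

Each stage is a pure function of (inputs, config, seed); a run directory
collects every stage's table plus a manifest recording the config hash,
input checksums and per-stage record counts, so identical configs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import afd as afd_mod
from . import fst as fst_mod
from . import genes as genes_mod
from . import integrate as integrate_mod
from . import phenotypes as pheno_mod
from .io import FilterParams, apply_site_filters, file_sha256, read_gene_models, read_mask, read_pool_sites

log = logging.getLogger(__name__)

STAGES = ("filter", "afd", "fst", "map-genes", "integrate", "enrich")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat configuration of one scan run (every key overridable from the CLI)."""

    sites: str = ""
    format: str | None = None  # sync | vcf | None = infer
    gff: str = ""
    mask: str | None = None
    de_list: str | None = None
    terms: str | None = None
    phenotypes: str | None = None
    scaffolds: str | None = None  # two-column name<TAB>length table
    outdir: str = "poolscan_run"
    pools: tuple[str, ...] = ("hypo", "hyper", "control")
    treatments: tuple[str, ...] = ("hypo", "hyper")
    control: str = "control"
    seed: int = 0
    pool_size: int = 46
    afd_threshold: float = 0.6
    afd_flank_bp: int = 0
    afd_gene_mode: str = "overlap"
    window_size: int = 1000
    top_fraction: float = 0.01
    flank_bp: int = 5000
    estimator: str = "hudson"
    min_snps: int = 1
    min_depth: int = 2
    min_depth_het: int = 3
    max_depth_factor: float = 3.0
    min_base_quality: float = 20.0
    exclude_ssr: bool = True

    def validate(self) -> None:
        if not 0 <= self.afd_threshold <= 1:
            raise ValueError(f"afd_threshold must lie in [0, 1] (got {self.afd_threshold})")
        if not 0 < self.top_fraction <= 1:
            raise ValueError(f"top_fraction must lie in (0, 1] (got {self.top_fraction})")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.flank_bp < 0 or self.afd_flank_bp < 0:
            raise ValueError("flanks must be >= 0")
        if self.estimator not in fst_mod.ESTIMATORS:
            raise ValueError(f"estimator must be one of {fst_mod.ESTIMATORS}")
        if self.control in self.treatments:
            raise ValueError("control pool cannot also be a treatment")
        for p in (*self.treatments, self.control):
            if p not in self.pools:
                raise ValueError(f"population {p!r} not among pools {self.pools}")
        self.filter_params()  # raises on bad thresholds
        for name in ("sites", "gff"):
            path = getattr(self, name)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"required input {name!r} missing: {path!r}")
        for name in ("mask", "de_list", "terms", "phenotypes", "scaffolds"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input {name!r} does not exist: {path}")

    def filter_params(self) -> FilterParams:
        return FilterParams(
            min_depth=self.min_depth,
            min_depth_het=self.min_depth_het,
            max_depth_factor=self.max_depth_factor,
            min_base_quality=self.min_base_quality,
            exclude_ssr=self.exclude_ssr,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pools"] = list(self.pools)
        d["treatments"] = list(self.treatments)
        return d

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key-value (YAML) config; keyword overrides win."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("pools", "treatments"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _read_scaffold_lengths(path: str | None) -> dict[str, int] | None:
    if path is None:
        return None
    lengths = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, length = line.split("\t")[:2]
                lengths[name] = int(length)
    return lengths


def _tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "inputs": {},
        "stages": {},
        "failed": None,
    }
    for name in ("sites", "gff", "mask", "de_list", "terms", "phenotypes", "scaffolds"):
        path = getattr(config, name)
        if path:
            manifest["inputs"][name] = {"path": str(path), "sha256": file_sha256(path)}

    current = "setup"
    try:
        scaffold_lengths = _read_scaffold_lengths(config.scaffolds)
        sites = read_pool_sites(config.sites, format=config.format, pools=config.pools)
        gene_models = read_gene_models(config.gff, scaffold_lengths)
        mask = read_mask(config.mask) if config.mask else None
        de_genes = afd_mod.read_gene_list(config.de_list) if config.de_list else []
        terms = pd.read_csv(config.terms, sep="\t") if config.terms else None

        current = "filter"
        filtered, report = apply_site_filters(sites, config.filter_params(), mask)
        _tsv(filtered, outdir / "filtered_sites.tsv")
        manifest["stages"]["filter"] = {
            "n_input": report.n_input,
            "removed": report.removed,
            "n_pass": report.n_pass,
        }
        log.info("filter: %d in, %d pass (%s)", report.n_input, report.n_pass, report.removed)

        background = sorted(g.gene_id for g in gene_models)
        for treatment in config.treatments:
            current = "afd"
            afd_table = afd_mod.scan_afd(filtered, treatment, config.control, config.afd_threshold)
            _tsv(afd_table, outdir / f"afd_{treatment}.tsv")
            afd_gene_set = afd_mod.afd_genes(
                afd_table, gene_models, flank_bp=config.afd_flank_bp, mode=config.afd_gene_mode
            )
            afd_mod.write_gene_list(afd_gene_set, outdir / f"afd_genes_{treatment}.txt")
            manifest["stages"].setdefault("afd", {})[treatment] = {
                "n_snps": int(len(afd_table)),
                "n_differentiated": int(afd_table["passes"].sum()),
                "n_genes": len(afd_gene_set),
            }

            current = "fst"
            site_comp = fst_mod.sites_fst(
                filtered, treatment, config.control, config.pool_size, config.estimator
            )
            windows = fst_mod.window_fst(
                site_comp, config.window_size, scaffold_lengths, config.min_snps
            )
            _tsv(windows, outdir / f"windows_{treatment}.tsv")
            top = fst_mod.select_top_windows(windows, config.top_fraction)
            fst_mod.write_windows_bed(top, outdir / f"outlier_windows_{treatment}.bed")
            manifest["stages"].setdefault("fst", {})[treatment] = {
                "n_windows": int(windows["rank"].notna().sum()),
                "n_outlier_windows": int(len(top)),
            }

            current = "map-genes"
            fst_gene_set = genes_mod.genes_overlapping_windows(
                top, gene_models, config.flank_bp, scaffold_lengths
            )
            afd_mod.write_gene_list(fst_gene_set, outdir / f"fst_genes_{treatment}.txt")
            manifest["stages"].setdefault("map-genes", {})[treatment] = {
                "n_genes": len(fst_gene_set)
            }

            current = "integrate"
            merged = integrate_mod.merge_differentiated(
                afd_gene_set, fst_gene_set, label=f"differentiated_{treatment}"
            )
            venn = integrate_mod.venn3(afd_gene_set, fst_gene_set, de_genes)
            _tsv(integrate_mod.venn_report(venn), outdir / f"venn_{treatment}.tsv")
            afd_mod.write_gene_list(venn.candidates, outdir / f"candidates_{treatment}.txt")
            manifest["stages"].setdefault("integrate", {})[treatment] = {
                "n_differentiated": len(merged.genes),
                "n_candidates": len(venn.candidates),
            }

            current = "enrich"
            if terms is not None:
                cand_in_bg = venn.candidates & set(background)
                enr = integrate_mod.enrich_terms(cand_in_bg, background, terms)
                _tsv(enr, outdir / f"enrichment_{treatment}.tsv")
                manifest["stages"].setdefault("enrich", {})[treatment] = {
                    "n_terms": int(len(enr)),
                    "n_significant": int((enr["p_adjusted"] < 0.05).sum()) if len(enr) else 0,
                }

        if config.phenotypes:
            current = "pheno"
            traits = pd.read_csv(config.phenotypes, sep="\t")
            rates = pheno_mod.compute_rates(traits)
            _tsv(rates, outdir / "phenotype_rates.tsv")
            _tsv(pheno_mod.trait_report(rates), outdir / "phenotype_anova.tsv")
            manifest["stages"]["pheno"] = {"n_rows": int(len(rates))}
    except Exception as exc:
        manifest["failed"] = current
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise PipelineStageError(current, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
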