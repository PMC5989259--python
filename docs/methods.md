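# Methods

## The scan

The pipeline detects population differentiation between pooled samples of
a treatment and a control population along two complementary routes, then
intersects the results with expression evidence.

**Allele frequencies from pools.** With reads sampled from a pool of `2N`
chromosomes, the alternate-allele frequency estimate is simply
`alt / (alt + ref)`. Its sampling variance has two stages: the binomial
draw of chromosomes into the sequenced pool and the binomial draw of reads
from the pool, giving `Var(p̂) = pq·(d + 2N − 1)/(2N·d)` at depth `d`. The
generator reproduces exactly this two-stage structure.

**AFD rule.** A SNP is *differentiated* when the absolute frequency
difference between treatment and control strictly exceeds 0.6. The strict
inequality follows the rule's wording ("above 0.6"); the threshold is a
parameter. Each treatment is compared with the control independently,
producing one differentiated set per treatment. AFD-based gene assignment
uses flank 0 by default; a nearest-gene mode exists because differentiated
SNP tables conventionally list a gene even for intergenic SNPs.

**F_ST estimator.** No estimator is canonical for pooled data; the package
defaults to a Hudson-type estimator with finite-sample correction
(numerator `(p₁−p₂)² − p₁q₁/(n₁−1) − p₂q₂/(n₂−1)`, denominator
`p₁q₂ + p₂q₁`) because it is robust to unequal sample sizes and does not
require allele-count likelihoods. A Nei/Wright heterozygosity-partition
form (no sample-size correction) is available behind `estimator="nei"` for
sensitivity checks and is deliberately *not* used as the default. The
effective per-pool sample size is `min(2·pool_size, depth)`: reads cannot
carry more information than the chromosomes in the pool. This rule
slightly under-corrects at depths below `2N` (the exact two-stage
effective size is `2N·d/(2N+d−1)`), which is why calibration runs at a
true F of 0.10 measure ≈ 0.105–0.112 rather than 0.100; the bias is
well inside the ±0.02 calibration band and the simpler rule is kept.

**Windows.** Sites aggregate into non-overlapping 1-kb tiles anchored at
each scaffold start, as the plain reading of "all 1000-bp windows";
sliding windows would correlate adjacent ranks and complicate the top-1 %
semantics. The window statistic is the ratio of summed numerators to
summed denominators (ratio of averages), the standard low-noise choice.
Windows without SNPs are reported but never ranked; negative site
numerators (noise under no differentiation) are retained in the sums so
ranking stays unbiased, and the displayed window value is floored at zero.
The top `ceil(0.01 · n_ranked)` windows are outliers, ties resolved by
(scaffold, start) so selection is deterministic.

**Integration and enrichment.** Candidate genes are
`(AFD ∪ FST) ∩ DE`. Enrichment is the one-sided hypergeometric tail
`P(X ≥ k)` per term against a background of all annotated genes (the
background is configurable; "all annotated genes" is the neutral default
when no assay universe is stated), BH-adjusted, reported significant below
adjusted p 0.05. GO/COG/KEGG are deliberately out of scope: term
annotations are a plain two-column input table, removing any dependence on
database versions.

**Phenotypes.** Rates are per-replicate ratios; growth defaults to
relative shell-height gain `(after − before)/before` (an absolute-gain
mode exists) since only a dimensionless rate is comparable across groups.
The omnibus test is a classical one-way ANOVA computed from explicit
between/within sums of squares; the F-distribution tail comes from SciPy.
Post hoc pairwise comparisons use Welch t-tests with BH adjustment —
pairwise annotations in this kind of assay imply some post hoc procedure,
and Welch avoids assuming equal group variances. Stars follow the usual
convention (\* p < 0.05, \*\* p < 0.01). qPCR fold change is `2^−ΔΔCt`.

## Coordinate and filtering conventions

Internally every interval is 0-based half-open; conversion happens exactly
once at file boundaries (sync/VCF positions and GFF3 intervals are 1-based
in files, BED is native). Shared boundaries do not overlap.

Site filters run per pool in a fixed order — minimum depth, heterozygous
minimum depth, maximum depth, base quality, SSR mask — and a removed site
is attributed to the first rule it fails, so the report always conserves
counts (input = passing + Σ removed). Two under-specified points were
resolved as follows: a pool is *heterozygous* at a site when both alleles
have at least one read (the only observable analogue in pooled counts),
and the 3× maximum-depth rule uses each pool's own mean depth over the
pre-filter table (the conservative per-pool reading). Sync files carry no
base qualities, so quality is missing there and the quality rule passes
vacuously; VCF input carries QUAL.

## The synthetic study generator

The generator emulates a three-population pooled design (two adapted
treatment lines, one control; 46 diploids per pool; truncated-Poisson
depth with mean 35×, matching a 10–40× depth profile) over a toy genome of
ten 100-kb scaffolds — 1,000 analysis windows — with 5,000 SNPs, 200
non-overlapping genes of 2–4 kb with 2–4 exons, an SSR mask covering 5 %
of the genome, 25 annotation terms, and larval phenotype tables.

**Background model.** Each population's frequency at a neutral locus is an
independent Balding–Nichols draw around an ancestral frequency
p₀ ~ U(0.05, 0.95): `p ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)` with
F = 0.05 by default (F = 0 degenerates to a point mass). Under this model
`E[(p₁−p₂)²] = 2F·p₀q₀` and `E[p₁(1−p₂)+p₂(1−p₁)] = 2p₀q₀`, so the
Hudson ratio-of-sums converges to F — the basis of the calibration check.

**Planted outliers as sweeps.** Outlier loci model completed selective
sweeps in one designated treatment population: the swept population's
frequency is drawn from the same beta family around the *swept* value
1 − p₀ (with divergence F_out = 0.6), with the outlier ancestral frequency
drawn low (U(0.05, 0.15)) and the whole locus rejection-resampled until
the realized treatment–control contrast reaches `min_outlier_afd`
(default 0.8). An unconditioned Balding–Nichols draw at F_out = 0.6 is
bidirectional and leaves a substantial fraction of "outliers" with small
contrasts, which would make the planted truth unusable as an oracle; the
guaranteed-contrast sweep matches what a scan of this design is meant to
find. Outlier loci are clustered into 5 sweep blocks (emulating linkage
around a swept site), each block a single window-length tile placed inside
a gene and outside the SSR mask — inside a gene so gene-level recovery is
well-defined, aligned to the analysis tiling so the truth table maps each
sweep to exactly one window, and outside the mask because masked regions
are excluded from the scan by design.

**Reads.** Depth per site and pool is Poisson(35) truncated at ≥ 1; the
alternate read count is binomial at the realized pool frequency k/2N,
where k is itself binomial(2N, p) — the two-stage pooled sampling above.
Base qualities are N(36, 3) clipped to [2, 41].

**Annotations and DE list.** Genes are placed by multinomial gap
allocation (uniform non-overlapping placement); exon/intron chunks get
multinomial widths with a 50-bp minimum. The DE list contains a fraction
`de_overlap_fraction` (default 0.5) of the sweep genes plus 10 % of the
remaining genes; with the default the integration step has both
recoverable and expression-silent sweep genes, while validation runs use
1.0 so end-to-end recovery is measurable against the full truth.

**Phenotypes.** Group means/sds for the four larval traits are plausible
synthetic conditions (e.g. control survival 0.40, adapted lines 0.48–0.52,
sd 0.04 on the rate scale), not measurements: the original assay's raw
values are unpublished, so these tables exercise the statistics without
claiming to reproduce any published effect. Count traits draw a binomial
numerator at a jittered per-replicate rate; growth draws shell heights
around 70 µm.

**Determinism.** Every artifact draws from a named substream of a single
seed (`numpy.random.SeedSequence` spawn keys), so identical parameters
give byte-identical files and any single output can be regenerated in
isolation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level errors and mapping artifacts, indels,
linkage disequilibrium beyond the sweep blocks, coalescent genealogies,
variable gene density, multi-allelic sites (the parser drops them, the
generator never emits them), and any real relationship between expression
and sequence differentiation (DE membership is assigned, not simulated
from a transcriptional model).

## Problem sizes and numerical choices

Validation runs use the default 1-Mb genome (1,000 windows, 5,000 SNPs)
and a 10,000-locus null genome for calibration; both finish in seconds and
give the recovery and calibration margins shown by the acceptance script.
Ties in window ranking are broken by coordinates; the hypergeometric tail
uses `scipy.stats.hypergeom.sf(k−1, …)` (exact to enumeration within
1e-12 for backgrounds ≤ 200); ANOVA requires non-zero within-group
variance and ≥ 2 replicates per group and errors otherwise; frequency
computation refuses zero-depth sites (they should have been filtered).
The sweep rejection loop converges in a handful of iterations because the
acceptance probability per draw is ≈ 0.7 under the default parameters;
a guard raises after 1,000 iterations rather than looping silently.

## Known limitations

* The effective-size rule `min(2N, d)` leaves a small upward F_ST bias at
  depths below 2N (quantified above); acceptable for ranking-based outlier
  detection, not for unbiased point estimation of F_ST.
* The AFD rule is a plain threshold; no significance is attached (CMH or
  Fisher tests on pooled counts are out of scope).
* Filters are applied per pool; whether the original procedure pooled
  depth across populations is unknowable from its description, and the
  per-pool reading is the conservative one.
* Enrichment treats terms independently (no GO-graph propagation or
  pathway topology).
* The window scan assumes a fixed window size; no haplotype-based or
  coalescent-null significance testing is provided.
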