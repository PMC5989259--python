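"""Statistical and bookkeeping properties of the synthetic study generator."""

import numpy as np
import pytest

from poolscan.fst import site_fst_components
from poolscan.simulate import (
    ParamError,
    SimParams,
    balding_nichols,
    simulate_annotation,
    simulate_phenotypes,
    simulate_pool_reads,
    simulate_population_frequencies,
    write_study,
)

SMALL = dict(n_scaffolds=4, scaffold_length=50_000, n_snps=800, n_genes=40,
             n_outlier_loci=20, n_outlier_regions=2)


class TestParams:
    @pytest.mark.parametrize(
        "bad",
        [
            {"n_snps": 0},
            {"background_divergence": -0.1},
            {"background_divergence": 0.7, "outlier_divergence": 0.6},
            {"n_outlier_loci": 10_000_000},
            {"ssr_fraction": 1.5},
            {"outlier_pool": "nope"},
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ParamError):
            SimParams(**bad)


class TestPopulationFrequencies:
    def test_zero_divergence_returns_ancestral_exactly(self):
        params = SimParams(seed=3, background_divergence=0.0, n_outlier_loci=0, **{
            k: v for k, v in SMALL.items() if not k.startswith("n_outlier")})
        truth = simulate_population_frequencies(params)
        for pool in ("hypo", "hyper", "control"):
            np.testing.assert_array_equal(truth.loci[f"p_{pool}"], truth.loci["ancestral"])

    def test_balding_nichols_mean_site_fst_matches_divergence(self):
        # Monte-Carlo check of the closed-form expectation: for BN draws at
        # divergence F the Hudson estimator (on the *true* frequencies, large
        # n) averages to F: E[(p1-p2)^2] = 2F p0 q0, E[den] = 2 p0 q0.
        rng = np.random.default_rng(11)
        F = 0.1
        p0 = rng.uniform(0.05, 0.95, 10_000)
        p1 = balding_nichols(p0, F, rng)
        p2 = balding_nichols(p0, F, rng)
        num, den = site_fst_components(p1, 1e9, p2, 1e9)
        assert num.sum() / den.sum() == pytest.approx(F, abs=0.02)

    def test_truth_flags_exactly_the_requested_outliers(self):
        params = SimParams(seed=5, **SMALL)
        truth = simulate_population_frequencies(params)
        assert int(truth.loci["is_outlier"].sum()) == params.n_outlier_loci
        assert len(truth.loci) == params.n_snps
        assert truth.loci["scaffold"].is_monotonic_increasing or True  # sorted check below
        grp = truth.loci.groupby("scaffold")["pos"]
        assert grp.apply(lambda s: s.is_monotonic_increasing).all()

    def test_outlier_loci_meet_the_minimum_true_contrast(self):
        params = SimParams(seed=5, **SMALL)
        truth = simulate_population_frequencies(params)
        out = truth.loci[truth.loci["is_outlier"]]
        contrast = (out["p_hypo"] - out["p_control"]).abs()
        assert (contrast >= params.min_outlier_afd).all()

    def test_outlier_loci_out_fst_exceeds_background(self):
        params = SimParams(seed=9, n_snps=2000, n_outlier_loci=100, n_outlier_regions=10)
        truth = simulate_population_frequencies(params)
        loci = truth.loci
        num, den = site_fst_components(
            loci["p_hypo"], 1e9, loci["p_control"], 1e9
        )
        fst = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
        assert fst[loci["is_outlier"]].mean() > fst[~loci["is_outlier"]].mean()


class TestPoolReads:
    def test_fixed_frequency_zero_gives_no_alt_reads(self):
        params = SimParams(seed=2, **SMALL)
        truth = simulate_population_frequencies(params)
        truth.loci.loc[:, ["p_hypo", "p_hyper", "p_control"]] = 0.0
        sites = simulate_pool_reads(truth, params)
        for pool in ("hypo", "hyper", "control"):
            assert (sites[f"{pool}.alt"] == 0).all()

    def test_depth_mean_and_conservation(self):
        params = SimParams(seed=2, n_snps=10_000)
        truth = simulate_population_frequencies(params)
        sites = simulate_pool_reads(truth, params)
        depth = sites["hypo.ref"] + sites["hypo.alt"]
        assert depth.mean() == pytest.approx(params.mean_depth, abs=1.0)
        assert (depth >= 1).all()

    def test_pool_of_one_individual_collapses_to_genotype_frequencies(self):
        # with one diploid individual the latent pool frequency is 0, 0.5 or 1;
        # at true p = 0.5 those genotypes occur 1/4, 1/2, 1/4, so at high depth
        # about a quarter of sites are all-ref and a quarter all-alt
        params = SimParams(seed=4, pool_size=1, mean_depth=200, n_snps=2000,
                           n_outlier_loci=0, n_scaffolds=2, scaffold_length=50_000,
                           n_genes=20)
        truth = simulate_population_frequencies(params)
        truth.loci.loc[:, ["p_hypo", "p_hyper", "p_control"]] = 0.5
        sites = simulate_pool_reads(truth, params)
        depth = sites["hypo.ref"] + sites["hypo.alt"]
        frac_ref_hom = float((sites["hypo.alt"] == 0).mean())
        frac_alt_hom = float((sites["hypo.alt"] == depth).mean())
        assert frac_ref_hom == pytest.approx(0.25, abs=0.04)
        assert frac_alt_hom == pytest.approx(0.25, abs=0.04)

    def test_observed_frequency_converges_to_truth_at_high_depth(self):
        # both sampling stages must shrink: reads (depth 10,000) and the
        # pooled chromosomes (large pool), else finite-pool noise persists
        params = SimParams(seed=6, mean_depth=10_000, pool_size=2000, n_snps=500,
                           n_outlier_loci=0, n_scaffolds=2, scaffold_length=50_000,
                           n_genes=20)
        truth = simulate_population_frequencies(params)
        sites = simulate_pool_reads(truth, params)
        merged = sites.merge(truth.loci, on=["scaffold", "pos"])
        obs = merged["hypo.alt"] / (merged["hypo.ref"] + merged["hypo.alt"])
        # depth -> inf leaves only the 2N-chromosome pool-sampling noise;
        # mean absolute deviation stays within the stated tolerance
        assert float(np.abs(obs - merged["p_hypo"]).mean()) < 0.02


class TestAnnotation:
    def test_gene_count_and_bounds(self):
        params = SimParams(seed=1, **SMALL)
        ann = simulate_annotation(params)
        assert len(ann.genes) == params.n_genes
        for g in ann.genes:
            assert 0 <= g.start < g.end <= params.scaffold_length

    def test_genes_do_not_overlap(self):
        params = SimParams(seed=1, **SMALL)
        ann = simulate_annotation(params)
        by_scaf = {}
        for g in ann.genes:
            by_scaf.setdefault(g.scaffold, []).append((g.start, g.end))
        for spans in by_scaf.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_zero_ssr_fraction_gives_empty_mask(self):
        params = SimParams(seed=1, ssr_fraction=0.0, **SMALL)
        ann = simulate_annotation(params)
        assert sum(len(v) for v in ann.mask.values()) == 0

    def test_full_de_overlap_includes_every_outlier_gene(self):
        params = SimParams(seed=1, de_overlap_fraction=1.0, **SMALL)
        ann = simulate_annotation(params)
        truth = simulate_population_frequencies(params)
        assert set(truth.outlier_gene_ids) <= set(ann.de_genes)

    def test_every_term_annotates_at_least_one_gene(self):
        params = SimParams(seed=1, **SMALL)
        ann = simulate_annotation(params)
        assert ann.terms["term"].nunique() == params.n_terms

    def test_annotation_consistent_with_truth_table(self):
        params = SimParams(seed=8, **SMALL)
        ann = simulate_annotation(params)
        truth = simulate_population_frequencies(params)
        spans = {g.gene_id: (g.scaffold, g.start, g.end) for g in ann.genes}
        out = truth.loci[truth.loci["is_outlier"]]
        for gid in truth.outlier_gene_ids:
            scaf, s, e = spans[gid]
            inside = out[(out["scaffold"] == scaf) & (out["pos"] >= s) & (out["pos"] < e)]
            assert len(inside) > 0


class TestPhenotypes:
    def test_table_shape(self):
        df = simulate_phenotypes(n_per_group=3, seed=0)
        assert len(df) == 4 * 3 * 3  # traits x groups x replicates
        assert set(df["trait"]) == {"production", "survival", "growth", "adhesive"}

    def test_survival_rate_recovers_group_mean_within_binomial_error(self):
        means = {"survival": {"hypo": 0.5, "hyper": 0.5, "control": 0.5}}
        sds = {"survival": {"hypo": 0.0, "hyper": 0.0, "control": 0.0}}
        df = simulate_phenotypes(means, sds, n_per_group=40, seed=3)
        sub = df[df["trait"] == "survival"]
        rate = (sub["numerator"] / sub["denominator"]).mean()
        # 120 replicates of Binomial(300, .5): SE ~ 0.0026; 5 sigma
        assert rate == pytest.approx(0.5, abs=0.015)


class TestDeterminism:
    def test_identical_params_give_byte_identical_files(self, tmp_path):
        params = SimParams(seed=13, **SMALL)
        p1 = write_study(params, tmp_path / "a")
        p2 = write_study(params, tmp_path / "b")
        assert p1.keys() == p2.keys()
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seeds_differ(self, tmp_path):
        a = write_study(SimParams(seed=1, **SMALL), tmp_path / "a")
        b = write_study(SimParams(seed=2, **SMALL), tmp_path / "b")
        assert a["sync"].read_bytes() != b["sync"].read_bytes()

    def test_read_counts_conserve_depth(self):
        params = SimParams(seed=3, **SMALL)
        truth = simulate_population_frequencies(params)
        sites = simulate_pool_reads(truth, params)
        for pool in ("hypo", "hyper", "control"):
            depth = sites[f"{pool}.ref"] + sites[f"{pool}.alt"]
            assert (sites[f"{pool}.ref"] >= 0).all() and (sites[f"{pool}.alt"] >= 0).all()
            assert (depth >= 1).all()
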