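"""Generator determinism, planted-truth bookkeeping and marginal statistics."""

import numpy as np
import pandas as pd
import pytest

from hmctools import (
    GenomicInterval,
    SimConfig,
    fisher_enrichment,
    gen_expression_and_links,
    gen_genome,
    gen_region_counts,
    gen_site_counts,
    gen_snp_catalog,
    gen_spikeins,
)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"p_bg": 0.5, "p_true": 0.4},          # background above signal
        {"p_true": 1.2},
        {"planted_fc": 1.0},
        {"depth_mean": 0},
        {"base_lambda": 0},
        {"link_r": 0.0},
        {"chrom_lengths": {"chr1": 0}},
        {"chrom_lengths": {}},
        {"n_tissues": 1},
    ])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestGenome:
    def test_same_seed_identical_sequences(self):
        cfg = SimConfig(seed=11, chrom_lengths={"chr1": 50_000})
        g1, genes1 = gen_genome(cfg)
        g2, genes2 = gen_genome(cfg)
        assert g1 == g2 and genes1 == genes2
        g3, _ = gen_genome(SimConfig(seed=12, chrom_lengths={"chr1": 50_000}))
        assert g1 != g3

    def test_gene_bodies_within_chromosome(self):
        cfg = SimConfig(seed=3, chrom_lengths={"chr1": 300_000})
        genome, genes = gen_genome(cfg)
        assert genes, "expected at least one gene"
        for g in genes:
            assert 0 <= g.start < g.end <= 300_000
        # genes do not overlap
        spans = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_base_composition_uniform(self):
        # binomial CI: each base frequency 0.25 +/- 0.02 at 100 kb
        cfg = SimConfig(seed=5, chrom_lengths={"chr1": 100_000})
        genome, _ = gen_genome(cfg)
        seq = genome["chr1"]
        for base in "ACGT":
            assert seq.count(base) / len(seq) == pytest.approx(0.25, abs=0.02)


class TestSiteCounts:
    def test_deterministic_under_seed(self, small_config, small_genome):
        genome, _ = small_genome
        c1, t1, _ = gen_site_counts(small_config, genome)
        c2, t2, _ = gen_site_counts(small_config, genome)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_background_means_zero_conversions(self):
        cfg = SimConfig(seed=2, n_sites=500, p_bg=0.0,
                        chrom_lengths={"chr1": 200_000}, n_tissues=2)
        genome, _ = gen_genome(cfg)
        counts, truth, _ = gen_site_counts(cfg, genome)
        truth_mod = truth.set_index(["chrom", "pos", "strand"])["is_modified"]
        joined = counts.join(truth_mod, on=["chrom", "pos", "strand"])
        assert (joined.loc[~joined["is_modified"], "NT"] == 0).all()

    def test_modified_conversion_mean_matches_p_true(self):
        cfg = SimConfig(seed=4, n_sites=12_500, modified_fraction=0.8,
                        chrom_lengths={"chr1": 1_000_000}, n_tissues=2)
        genome, _ = gen_genome(cfg)
        counts, truth, _ = gen_site_counts(cfg, genome)
        truth_mod = truth.set_index(["chrom", "pos", "strand"])["is_modified"]
        joined = counts.join(truth_mod, on=["chrom", "pos", "strand"])
        mod = joined[joined["is_modified"]]
        assert len(mod) >= 10_000
        rate = mod["NT"].sum() / mod["N"].sum()
        assert rate == pytest.approx(cfg.p_true, abs=0.01)

    def test_symmetric_dyad_fraction_planted(self):
        cfg = SimConfig(seed=9, n_sites=12_000, modified_fraction=0.9,
                        cg_fraction=1.0, chrom_lengths={"chr1": 1_500_000},
                        n_tissues=2)
        genome, _ = gen_genome(cfg)
        _, truth, _ = gen_site_counts(cfg, genome)
        plus = truth[(truth["strand"] == "+") & truth["is_modified"]]
        minus = truth[(truth["strand"] == "-") & truth["is_modified"]]
        minus_keys = set(zip(minus["chrom"], minus["pos"] - 1))
        sym = sum((c, p) in minus_keys for c, p in zip(plus["chrom"], plus["pos"]))
        assert sym / len(plus) == pytest.approx(0.13, abs=0.02)

    def test_truth_positions_exist_in_counts(self, small_sites):
        counts, truth, _ = small_sites
        emitted = set(zip(counts["chrom"], counts["pos"], counts["strand"]))
        for row in truth.itertuples(index=False):
            assert (row.chrom, row.pos, row.strand) in emitted

    def test_depth_always_positive(self, small_sites):
        counts, _, _ = small_sites
        assert (counts["N"] >= 1).all()

    def test_context_consistent_with_genome(self, small_config, small_genome):
        from hmctools import classify_context
        genome, _ = small_genome
        _, truth, _ = gen_site_counts(small_config, genome)
        sample = truth.sample(n=200, random_state=0)
        for row in sample.itertuples(index=False):
            ctx, _ = classify_context(genome, row.chrom, row.pos, row.strand)
            assert ctx == row.context


class TestSpikeins:
    def test_rates_near_configured(self):
        cfg = SimConfig(seed=1)
        df = gen_spikeins(cfg, depth=20_000)
        hm = df[df["state"] == "5hmC"]
        ref = df[df["state"] == "unmodified"]
        assert hm["NT"].sum() / (hm["NT"] + hm["NC"]).sum() == pytest.approx(
            cfg.p_true, abs=0.01)
        assert ref["NT"].sum() / (ref["NT"] + ref["NC"]).sum() == pytest.approx(
            cfg.p_bg, abs=0.002)


class TestRegionCounts:
    def test_planting_is_exact(self, small_config, small_regions):
        _, truth = small_regions
        n_planted = (truth["specific_tissue"] != "").sum()
        assert n_planted == round(small_config.n_regions *
                                  small_config.planted_ts_fraction)

    def test_no_planting_when_fraction_zero(self):
        cfg = SimConfig(seed=2, n_regions=200, planted_ts_fraction=0.0,
                        chrom_lengths={"chr1": 1_000_000})
        _, truth = gen_region_counts(cfg)
        assert (truth["fold_change"] == 1.0).all()

    def test_nonspecific_mean_matches_base_lambda(self):
        cfg = SimConfig(seed=6, n_regions=1000, sf_range=(1.0, 1.0),
                        chrom_lengths={"chr1": 4_000_000})
        matrix, truth = gen_region_counts(cfg)
        null_regions = truth.loc[truth["specific_tissue"] == "", "region"]
        values = matrix.raw.loc[null_regions].to_numpy().ravel()
        tol = 3 * np.sqrt(cfg.base_lambda / values.size)
        assert values.mean() == pytest.approx(cfg.base_lambda, abs=tol)

    def test_determinism(self, small_config):
        m1, t1 = gen_region_counts(small_config)
        m2, t2 = gen_region_counts(small_config)
        pd.testing.assert_frame_equal(m1.raw, m2.raw)
        pd.testing.assert_frame_equal(t1, t2)


class TestExpressionAndLinks:
    def test_perfect_correlation_without_noise(self, small_genome, small_regions):
        _, genes = small_genome
        _, truth = small_regions
        cfg = SimConfig(seed=7, link_r=1.0)
        tpm, links = gen_expression_and_links(cfg, truth, genes)
        assert not links.empty
        for row in links.itertuples(index=False):
            t = truth.loc[truth["region"] == row.region].iloc[0]
            x = np.full(cfg.n_tissues, cfg.base_lambda)
            x[cfg.tissues.index(t.specific_tissue)] *= cfg.planted_fc
            r = np.corrcoef(x, tpm.loc[row.gene])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_planted_links_reach_target_correlation(self):
        cfg = SimConfig(seed=8, n_tissues=16, n_regions=60,
                        chrom_lengths={"chr1": 1_500_000, "chr2": 1_500_000})
        genome, genes = gen_genome(cfg)
        _, truth = gen_region_counts(cfg)
        tpm, links = gen_expression_and_links(cfg, truth, genes)
        assert len(links) >= 10
        ok = 0
        for row in links.itertuples(index=False):
            t = truth.loc[truth["region"] == row.region].iloc[0]
            x = np.full(cfg.n_tissues, cfg.base_lambda)
            x[cfg.tissues.index(t.specific_tissue)] *= cfg.planted_fc
            r = np.corrcoef(x, tpm.loc[row.gene])[0, 1]
            ok += 0.8 <= r <= 1.0
        assert ok / len(links) >= 0.9

    def test_unlinked_genes_uncorrelated(self):
        cfg = SimConfig(seed=8, n_tissues=16, n_regions=60,
                        chrom_lengths={"chr1": 1_500_000, "chr2": 1_500_000})
        genome, genes = gen_genome(cfg)
        _, truth = gen_region_counts(cfg)
        tpm, links = gen_expression_and_links(cfg, truth, genes)
        linked = set(links["gene"])
        spike = np.full(cfg.n_tissues, cfg.base_lambda)
        spike[0] *= cfg.planted_fc
        rs = [abs(np.corrcoef(spike, tpm.loc[g])[0, 1])
              for g in tpm.index if g not in linked]
        assert np.mean(rs) < 0.5


class TestSnpCatalog:
    def test_positions_within_bounds(self, small_regions, small_config):
        _, truth = small_regions
        snps, _ = gen_snp_catalog(small_config, truth)
        for chrom, group in snps.groupby("chrom"):
            assert group["pos"].min() >= 0
            assert group["pos"].max() < small_config.chrom_lengths[chrom]

    def test_no_planting_gives_unit_odds_ratio(self, small_regions):
        # large catalog: ~60 in-region SNPs expected per phenotype, so the
        # sample OR concentrates well within (0.5, 2)
        cfg = SimConfig(seed=13, n_regions=300, planted_or=1.0, n_snps=40_000,
                        chrom_lengths={"chr1": 400_000, "chr2": 400_000})
        _, truth = gen_region_counts(cfg)
        snps, snp_truth = gen_snp_catalog(cfg, truth)
        assert snp_truth["odds_ratio"] == 1.0
        target = truth[truth["specific_tissue"] == snp_truth["tissue"]]
        regions = [GenomicInterval(r.chrom, r.start, r.end)
                   for r in target.itertuples(index=False)]
        res = fisher_enrichment(snps, regions)
        planted = res[res["phenotype"] == snp_truth["phenotype"]].iloc[0]
        assert 0.5 < planted["odds_ratio"] < 2.0

    def test_planted_odds_ratio_recovered(self, small_config, small_regions):
        _, truth = small_regions
        snps, snp_truth = gen_snp_catalog(small_config, truth)
        target = truth[truth["specific_tissue"] == snp_truth["tissue"]]
        regions = [GenomicInterval(r.chrom, r.start, r.end)
                   for r in target.itertuples(index=False)]
        res = fisher_enrichment(snps, regions)
        planted = res[res["phenotype"] == snp_truth["phenotype"]].iloc[0]
        assert 5.0 <= planted["odds_ratio"] <= 20.0
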