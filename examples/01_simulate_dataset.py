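"""Generate a small synthetic hydroxymethylome with planted ground truth.

The generator emulates the data a base-resolution 5hmC profiling study
produces after alignment: per-cytosine C-to-T conversion counts, enrichment
peaks, a merged-region count matrix with tissue-specific regions, expression
tables and a SNP catalog. Every planted feature is recorded in truth tables.
"""

from hmctools import SimConfig, gen_genome, gen_region_counts, gen_site_counts

cfg = SimConfig(seed=1, n_sites=5000, n_regions=500,
                chrom_lengths={"chr1": 1_000_000, "chr2": 1_000_000})
genome, genes = gen_genome(cfg)
counts, site_truth, peaks = gen_site_counts(cfg, genome)
matrix, region_truth = gen_region_counts(cfg)

n_mod = site_truth["is_modified"].sum()
n_planted = (region_truth["specific_tissue"] != "").sum()
print(f"genome: {sum(cfg.chrom_lengths.values()):,} bp, {len(genes)} genes")
print(f"sites: {len(site_truth)} cytosines emitted, {n_mod} truly modified "
      f"({100 * counts[counts['NT'] > 0].shape[0] / len(counts):.0f}% of "
      "records show any conversion)")
print(f"regions: {cfg.n_regions} merged peaks, {n_planted} planted "
      f"tissue-specific at fold change {cfg.planted_fc}")
# The modified fraction and planted fraction are exact by construction;
# conversion counts are Binomial(depth, 0.9) at modified sites and
# Binomial(depth, 0.005) elsewhere, so downstream callers can be scored
# against the truth tables.
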