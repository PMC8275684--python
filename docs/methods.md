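# Methods

`hmctools` implements the downstream statistics of a base-resolution,
bisulfite-free 5-hydroxymethylcytosine (5hmC) profiling workflow: the
chemistry selectively converts 5hmC so it reads as T, and everything after
alignment — calibration, site calling, differential-region detection,
gene linkage and SNP enrichment — is statistical. This note records the
models, the defaults and the design choices that were genuinely open.

## Conversion model and site calling

Each cytosine in a sample carries counts `NT` (converted, read as T) and
`NC` (unconverted), with depth `N = NT + NC`. Two rates are calibrated from
spike-in controls included in library construction:

- `p_true` — conversion at a fully hydroxymethylated spike-in cytosine,
  estimated as the pooled ratio `sum(NT) / sum(NT + NC)` over modified
  spike-in sites (typically ~0.9);
- `p_bg` — background conversion at unmodified spike-in cytosines,
  estimated the same way (typically ~0.005). Calibration fails loudly if
  `p_bg >= p_true`, which indicates failed chemistry.

A site's evidence is the exact binomial upper tail `P(X >= NT)` for
`X ~ Binomial(N, p_bg)`, computed through the regularized incomplete beta
function; tails below 1e-300 are reported as 0. Sites with `N < 5` or
`NT < 3` are discarded before testing. Family-wise error is controlled by
Holm's step-down procedure at `alpha = 0.001`, and calls are additionally
gated on membership in an enrichment peak of the same tissue (the union of
the tissue's replicate peaks).

**Multiplicity family.** The coverage filter (`NT >= 3`) is itself a
data-dependent selection: under pure background at depth 20, a site passes
it with probability ~1.5e-4, and any site that passes already has a raw
p-value of that order. If the Holm family contained only the filter's
survivors, the family would shrink to a handful of tests and the
probability of at least one false call over the sites examined would be far
above `alpha`. The family size therefore defaults to **all sites of the
sample present in the input** (the sites examined), with the
filter-survivors-only family available as `family_members="tested"` and a
`per-tissue` scope flag for pooling a tissue's samples. The read-level
filter keeps read pairs with at least one C-to-T conversion
(`min_conversions = 1`, configurable), since conversion-free fragments
carry no 5hmC evidence.

Context classification follows the usual CG / CHG / CHH scheme (H is A, C
or T), evaluated on the reverse complement for minus-strand cytosines; a
CpG dyad is symmetric when both the plus-strand C at `x` and the
minus-strand C at `x + 1` are called.

## tsDhMR detection

Peaks from all samples are merged (union of overlapping-or-touching
intervals) into one region set. Per-region raw counts are normalized by
median-of-ratios size factors: the per-region reference is the geometric
mean across samples (regions containing any zero are excluded), and a
sample's factor is the median over regions of `count / reference`, taken on
the ratio scale. Replicates of a tissue are then averaged (mean is the
default; `sum` is available — averaging keeps the tissue value on the scale
of a single library, which is what the Poisson tail assumes).

Each (region, tissue) pair is tested one-vs-rest: the rate `lambda` is the
mean of the other tissues' merged values and the p-value is the upper
Poisson tail `P(X >= count)`. Numerical conventions:

- normalized counts are non-integer; they are floored before the exact
  tail, which is conservative for an upper tail (a continuous alternative
  was considered and rejected as unnecessary — flooring changes the tail by
  less than one count);
- when the other tissues are empty, `lambda` is replaced by a pseudocount
  `lambda_min = 0.5` to avoid p = 0 artifacts.

P-values are Bonferroni-adjusted over all `regions x tissues` tests by
default (`family="per-tissue"` adjusts over regions only). A region is a
tsDhMR in a tissue when adjusted `P < 0.05` **and** fold change
(`count / lambda`) exceeds 2; a region may be specific to more than one
tissue. Fold change is computed on normalized counts. The fold-change
requirement dominates in practice: at `lambda = 50` a null region would
need to double its signal, which is far beyond the Poisson tail at any
plausible multiplicity threshold, so the caller's family-wise false-call
rate sits well below the nominal 0.05.

## Annotation

Gene models induce four classes — promoter (TSS ± 2 kb), exon, intron,
intergenic — flattened by the precedence promoter > exon > intron >
intergenic so they partition the genome. Peaks are classified at their
midpoint (single-label output, matching the usual pie-chart summaries).
Per-class enrichment is `log2(obs / exp)` where `obs` is the fraction of
queries in the class and `exp` the fraction of genome bp it covers; classes
with no observations report `-inf`.

## Expression and linkage

Tissue-specifically expressed genes: drop genes with mean TPM < 1, compute
fold change of each gene in a tissue over the mean of the other tissues,
rank per tissue, keep the top 300, then drop entries with fold change < 2
(rank-then-filter, in that order). Gene-body 5hmC signal is RPKM-like:
`counts / (gene length in kb x library size in millions)` over the full
annotated gene span (a promoter-exclusion variant can be built by adjusting
the gene models); correlation with expression uses Spearman's rho by
default.

Region-gene linkage: candidate pairs are (tsDhMR, gene) with the minimum
gap between the region interval and the gene TSS at most 500 kb
(inclusive — "within 500 kb" is read as a closed bound). For each pair,
Pearson r between the region's replicate-merged normalized signal and the
gene's TPM across tissues, with the two-sided t-test p-value
`t = r * sqrt(n - 2) / sqrt(1 - r^2)` on `n - 2` degrees of freedom
(perfect fits are reported at an underflow cap of 1e-300). A link is
confident when `r > 0.8` and `P < 0.05`. At least 4 tissues are required;
constant series are skipped with a warning.

## SNP enrichment

For each phenotype in a catalog, the 2x2 table counts the phenotype's SNPs
inside/outside the tsDhMR set against all other catalog SNPs (the universe
is the supplied catalog; a custom background can be passed as regions).
Significance is the one-sided (greater) Fisher exact test; the effect size
is the sample odds ratio `ad / bc`, with 0 / +inf sentinels at empty
margins. Benjamini-Hochberg adjusted values are reported as an extra
column; the raw p is primary. SNP positions are 0-based points against
half-open regions (a SNP at a region's start is inside, at its end
outside). LD structure is not modeled; see limitations.

## The synthetic-data generator

The generator plants known truth at every level so each caller can be
scored exactly. Defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| `p_true` / `p_bg` | 0.9 / 0.005 | conversion at 5hmC / background |
| `depth_mean` | 20 | per-site coverage, zero-truncated Poisson |
| `n_sites`, `modified_fraction` | 10 000, 0.2 | emitted cytosines; fraction truly modified |
| `cg_fraction` | 0.9846 | modified sites in CpG context |
| `symmetric_fraction` | 0.13 | modified CpG dyads marked on both strands |
| `n_tissues` x replicates | 8 x 2 | samples |
| `n_regions`, `region_length` | 3000, 1 kb | merged regions tiling the genome |
| `planted_ts_fraction`, `planted_fc` | 1/3, 5 | tissue-specific regions, one tissue each |
| `base_lambda` | 50 | mean region count at size factor 1 |
| `sf_range` | [0.5, 2] | per-sample size factors, log-uniform |
| `link_r` | 0.95 | expected Pearson r of planted region-gene links |
| `n_snps`, `planted_or` | 10 000, 10 | catalog size; generative odds ratio |

Mechanics worth noting:

- Coverage is a zero-truncated Poisson — the simplest model matching the
  caller's binomial assumption; real libraries are overdispersed.
- Modified CpG dyads emit the minus-strand partner record too (converting
  at `p_true` only for the symmetric fraction), so strand symmetry is
  measurable from calls.
- Region counts are `Poisson(base_lambda x fc x sf)`; replicates are
  independent. No extra-Poisson replicate variance is simulated, because
  the caller's test is exactly Poisson (a stated assumption, not a claim
  about real data).
- Planted links: each planted region is paired with the nearest free gene
  TSS within 500 kb; the gene's TPM is the region's measured signal plus
  Gaussian noise with sd `sd(signal) x sqrt(1 / link_r^2 - 1)`, which makes
  the expected Pearson r equal `link_r`. Unlinked genes draw a per-gene
  lognormal baseline with Gaussian tissue noise (cv 0.15). A heavy-tailed
  per-tissue draw was deliberately avoided: against the spiky one-vs-rest
  signal profile of a planted region, lognormal per-tissue noise produces
  spurious r > 0.8 at ~6e-3 per pair (measured), an artifact of the
  generator geometry rather than a property of the linker.
- SNP catalog: background phenotypes are uniform on the genome; the planted
  phenotype's SNPs fall inside one tissue's regions with the mixture weight
  solved so its total inside-probability yields the target odds ratio
  against a uniform background (the uniform branch itself lands inside with
  the coverage probability, which the solution accounts for).
- Toy genomes are uniform A/C/G/T with non-overlapping genes every
  ~30–120 kb (1–4 exons, random strand) — human-like gene density at toy
  scale, which keeps the number of candidate genes per 500-kb linkage
  window realistic. Genome composition, CpG islands, repeats and batch
  structure are not emulated; passing tests show the statistics recover
  what was planted under their own assumptions, not that the pipeline is
  robust to artifacts of real sequencing data.

All draws derive from a single seed through independent named streams, so
every output is bit-reproducible and stages can be regenerated separately.

## Validation problem sizes

The test suite validates exact tails against independent brute-force
summation (binomial N <= 50; Poisson lambda <= 50, count <= 200; Fisher
totals <= 500, all at 1e-10 relative error, with tails below ~1e-290
compared as zero since they leave the representable double range), Holm and
Bonferroni against literal definitions on 1000 random vectors, family-wise
error control of both callers over 200 null replicates, and planted-truth
recovery over 20 seeds per stage (3000 regions x 8 tissues x 2 replicates
for regions; 16 tissues x 60 regions for linkage; 10 phenotypes x 10 000
SNPs for enrichment). The permutation check of the Pearson p-value uses
10 000 shuffles at n = 8; the label-permutation uniformity check of the
Fisher p uses a 40 000-SNP catalog because the exact test's p-value is
discrete and only approaches uniformity when the overlap counts span many
lattice points.

## Known limitations

- Poisson replicate model: no dispersion parameter, unlike
  negative-binomial frameworks; with few replicates and real
  overdispersion the tsDhMR test would be anti-conservative.
- No LD pruning in SNP enrichment; correlated SNPs inflate effective
  counts.
- Per-site stoichiometry (the fraction of molecules modified) is not
  estimated — the binomial test detects presence, not level.
- The generator's marginal statistics match the configured values only in
  expectation at the stated tolerances; small configurations are noisy.
- Batch correction is intentionally absent from the region pipeline; the
  count model assumes library depth is the only technical covariate.
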