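"""Synthetic hydroxymethylome datasets with planted ground truth.

Every downstream stage of the pipeline is testable against data this module
generates: per-cytosine conversion counts with known modified sites, merged
regions with planted tissue-specific fold changes over Poisson replicate
counts, expression tables correlated with nearby region signal, and SNP
catalogs with a planted odds ratio. All draws flow from a single seed and are
bit-reproducible.

The generative model mirrors the assumptions of the callers it exercises:
conversion counts are Binomial(depth, p) with depth a zero-truncated Poisson;
region counts are Poisson with per-sample size factors log-uniform in a
stated range; planted regions are hyperhydroxymethylated in exactly one
tissue. Real sequencing data are overdispersed and batch-structured in ways
this model does not emulate (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, merge_intervals
from .regions import RegionCountMatrix

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults set to its conditions."""

    seed: int = 0
    n_tissues: int = 8
    n_replicates_per_tissue: int = 2
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 3_000_000, "chr2": 3_000_000})
    # site-level generative model
    p_true: float = 0.9            # conversion rate at true 5hmC sites
    p_bg: float = 0.005            # background conversion at unmodified C
    depth_mean: float = 20.0       # per-site coverage mean (truncated Poisson)
    n_sites: int = 10_000
    modified_fraction: float = 0.2
    cg_fraction: float = 0.9846    # modified sites in CG context
    symmetric_fraction: float = 0.13  # modified CpG dyads modified on both strands
    # region-level generative model
    n_regions: int = 3000
    region_length: int = 1000
    planted_ts_fraction: float = 1 / 3
    planted_fc: float = 5.0
    base_lambda: float = 50.0      # mean region count in non-specific tissues
    sf_range: tuple = (0.5, 2.0)   # per-sample size factors, log-uniform
    # expression / linkage
    link_r: float = 0.95           # target generative Pearson r of planted links
    # SNP catalog
    n_snps: int = 10_000
    n_phenotypes: int = 10
    planted_or: float = 10.0       # generative odds ratio of the planted phenotype

    def __post_init__(self) -> None:
        fractions = {"p_true": self.p_true, "p_bg": self.p_bg,
                     "planted_ts_fraction": self.planted_ts_fraction,
                     "cg_fraction": self.cg_fraction,
                     "symmetric_fraction": self.symmetric_fraction,
                     "modified_fraction": self.modified_fraction}
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.p_bg >= self.p_true:
            raise ValueError("require p_bg < p_true")
        if self.planted_fc <= 1:
            raise ValueError("planted_fc must exceed 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.base_lambda <= 0:
            raise ValueError("base_lambda must be positive")
        if not (0.0 < self.link_r <= 1.0):
            raise ValueError("link_r must lie in (0, 1]")
        if self.n_tissues < 2:
            raise ValueError("need at least two tissues")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be nonempty")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"zero-length chromosome {chrom!r}")
        if self.planted_or <= 0:
            raise ValueError("planted_or must be positive")

    @property
    def tissues(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_tissues)]

    @property
    def samples(self) -> list[str]:
        return [f"{t}_r{j + 1}" for t in self.tissues
                for j in range(self.n_replicates_per_tissue)]

    @property
    def sample_tissue(self) -> dict:
        return {s: s.rsplit("_r", 1)[0] for s in self.samples}

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic RNG stream for one generator stage."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


# RNG stream ids, one per stage so stages stay independent under one seed
_GENOME, _SITES, _REGIONS, _EXPR, _SNPS, _SPIKE = range(6)


# ---------------------------------------------------------------- genome

def gen_genome(config: SimConfig) -> tuple[dict, list[GeneModel]]:
    """Random A/C/G/T genome plus non-overlapping toy gene models.

    Genes are tiled along each chromosome with random lengths, gaps, strands
    and 1-4 exons, so every region simulated later has gene TSSs within
    linking distance.
    """
    rng = config.rng(_GENOME)
    genome = {}
    for chrom in sorted(config.chrom_lengths):
        n = config.chrom_lengths[chrom]
        genome[chrom] = rng.choice(_BASES, size=n).tobytes().decode()
    genes = []
    gid = 0
    for chrom in sorted(config.chrom_lengths):
        clen = config.chrom_lengths[chrom]
        pos = int(rng.integers(2_000, 20_000))
        while True:
            length = int(rng.integers(2_000, 12_000))
            if pos + length >= clen:
                break
            start, end = pos, pos + length
            n_exons = int(rng.integers(1, 5))
            cuts = np.sort(rng.choice(
                np.arange(start + 1, end), size=2 * (n_exons - 1),
                replace=False)) if n_exons > 1 else np.array([], dtype=int)
            bounds = np.concatenate(([start], cuts, [end]))
            exons = tuple((int(bounds[i]), int(bounds[i + 1]))
                          for i in range(0, len(bounds) - 1, 2))
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(GeneModel(f"gene_{gid:04d}", chrom, strand,
                                   start, end, exons=exons))
            pos = end + int(rng.integers(30_000, 120_000))
    return genome, genes


# ---------------------------------------------------------------- site counts

def _truncated_poisson(rng, mean, size) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1."""
    out = rng.poisson(mean, size=size)
    zeros = out == 0
    while zeros.any():
        out[zeros] = rng.poisson(mean, size=int(zeros.sum()))
        zeros = out == 0
    return out


def _cytosine_positions(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(plus-strand CpG C's, plus-strand CH C's with full context, CH contexts)."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_c = arr == b"C"
    is_g = arr == b"G"
    # exclude the last two bases so every context is classifiable
    valid = np.zeros(len(arr), dtype=bool)
    valid[: len(arr) - 2] = True
    cg = np.flatnonzero(is_c & np.roll(is_g, -1) & valid)
    ch = np.flatnonzero(is_c & ~np.roll(is_g, -1) & valid)
    ch_context = np.where(is_g[np.minimum(ch + 2, len(arr) - 1)], "CHG", "CHH")
    return cg, ch, ch_context


def gen_site_counts(config: SimConfig, genome: dict):
    """Per-cytosine conversion counts per sample, with site truth and peaks.

    Modified sites convert at p_true in every tissue; everything else at
    p_bg. One sample per tissue is emitted (site-level replicates add nothing
    the callers test). Also returns per-tissue peak sets: merged +/-75 bp
    windows around modified sites, emulating enrichment peaks.

    Returns (counts DataFrame, truth DataFrame, peaks_by_tissue dict).
    """
    rng = config.rng(_SITES)
    n_mod = int(round(config.n_sites * config.modified_fraction))
    n_unmod = config.n_sites - n_mod
    n_mod_cg = int(round(n_mod * config.cg_fraction))
    n_mod_ch = n_mod - n_mod_cg
    n_sym = int(round(n_mod_cg * config.symmetric_fraction))

    chroms = sorted(genome)
    records = []  # (chrom, pos, strand, context, modified, dyad_id)

    # partition candidate cytosines across chroms proportionally to length
    cg_pool, ch_pool = [], []
    for chrom in chroms:
        cg, ch, ch_ctx = _cytosine_positions(genome[chrom])
        cg_pool.append((chrom, cg))
        ch_pool.append((chrom, ch, ch_ctx))

    def draw(pool_sizes, n):
        """Split n draws across chroms proportional to pool size."""
        total = sum(pool_sizes)
        counts = np.floor(n * np.asarray(pool_sizes) / total).astype(int)
        counts[: n - counts.sum()] += 1
        return counts

    # modified CpG dyads (plus-strand C at x, minus-strand C at x+1)
    per_chrom = draw([len(cg) for _, cg in cg_pool], n_mod_cg)
    mod_cg = []
    for (chrom, cg), k in zip(cg_pool, per_chrom):
        chosen = rng.choice(cg, size=k, replace=False)
        mod_cg.extend((chrom, int(p)) for p in chosen)
    sym_flags = np.zeros(n_mod_cg, dtype=bool)
    sym_flags[rng.choice(n_mod_cg, size=n_sym, replace=False)] = True
    for i, (chrom, pos) in enumerate(mod_cg):
        records.append((chrom, pos, "+", "CG", True))
        # minus-strand partner: truly modified only at symmetric dyads
        records.append((chrom, pos + 1, "-", "CG", bool(sym_flags[i])))

    # modified CH sites
    per_chrom = draw([len(ch) for _, ch, _ in ch_pool], n_mod_ch)
    used_ch = {}
    for (chrom, ch, ch_ctx), k in zip(ch_pool, per_chrom):
        idx = rng.choice(len(ch), size=k, replace=False)
        used_ch[chrom] = set(ch[idx].tolist())
        for j in idx:
            records.append((chrom, int(ch[j]), "+", str(ch_ctx[j]), True))

    # unmodified background cytosines (mixed contexts, plus strand)
    used_cg = {chrom: set() for chrom in chroms}
    for chrom, pos in mod_cg:
        used_cg[chrom].add(pos)
    per_chrom = draw([len(cg) + len(ch) for (_, cg), (_, ch, _) in
                      zip(cg_pool, ch_pool)], n_unmod)
    for (chrom, cg), (_, ch, ch_ctx), k in zip(cg_pool, ch_pool, per_chrom):
        pool = np.concatenate([cg, ch])
        ctxs = np.concatenate([np.repeat("CG", len(cg)), ch_ctx])
        avoid = used_cg[chrom] | used_ch.get(chrom, set())
        keep = ~np.isin(pool, list(avoid))
        idx = rng.choice(np.flatnonzero(keep), size=k, replace=False)
        for j in idx:
            records.append((chrom, int(pool[j]), "+", str(ctxs[j]), False))

    truth = pd.DataFrame(records,
                         columns=["chrom", "pos", "strand", "context",
                                  "is_modified"])
    truth["tissue_set"] = np.where(truth["is_modified"],
                                   ",".join(config.tissues), "")

    # counts per tissue-sample
    frames = []
    n_rec = len(truth)
    p_site = np.where(truth["is_modified"], config.p_true, config.p_bg)
    for tissue in config.tissues:
        depth = _truncated_poisson(rng, config.depth_mean, n_rec)
        nt = rng.binomial(depth, p_site)
        frames.append(pd.DataFrame({
            "chrom": truth["chrom"], "pos": truth["pos"],
            "strand": truth["strand"], "context": truth["context"],
            "sample": tissue, "NT": nt, "NC": depth - nt}))
    counts = pd.concat(frames, ignore_index=True)
    counts["N"] = counts["NT"] + counts["NC"]

    # enrichment peaks: windows around modified sites, shared across tissues
    mod = truth[truth["is_modified"]]
    peak_ivs = [GenomicInterval(c, max(0, p - 75),
                                min(len(genome[c]), p + 76))
                for c, p in zip(mod["chrom"], mod["pos"])]
    merged = merge_intervals(peak_ivs)
    peaks_by_tissue = {t: merged for t in config.tissues}
    return counts, truth, peaks_by_tissue


def gen_spikeins(config: SimConfig, depth: int = 5000,
                 n_unmodified: int = 10) -> pd.DataFrame:
    """Spike-in calibration counts: one fully hydroxymethylated cytosine
    converting at p_true, plus unmodified control cytosines at p_bg."""
    rng = config.rng(_SPIKE)
    rows = [{"site_id": "spike_hmC_1", "state": "5hmC",
             "NT": int(rng.binomial(depth, config.p_true))}]
    for i in range(n_unmodified):
        rows.append({"site_id": f"spike_ref_{i + 1}", "state": "unmodified",
                     "NT": int(rng.binomial(depth, config.p_bg))})
    df = pd.DataFrame(rows)
    df["NC"] = depth - df["NT"]
    return df[["site_id", "state", "NT", "NC"]]


# ---------------------------------------------------------------- regions

def gen_region_counts(config: SimConfig):
    """Merged-region count matrix with planted tissue-specific regions.

    Regions tile the genome; an exact ``round(n_regions * planted_ts_fraction)``
    of them are specific to one tissue each (assigned round-robin) with
    counts ~ Poisson(base_lambda * planted_fc * sf) there and
    Poisson(base_lambda * sf) elsewhere. Size factors are log-uniform in
    ``sf_range``; replicates are independent.

    Returns (RegionCountMatrix, truth DataFrame).
    """
    rng = config.rng(_REGIONS)
    chroms = sorted(config.chrom_lengths)
    total = sum(config.chrom_lengths.values())
    per_chrom = {c: max(1, int(round(config.n_regions *
                                     config.chrom_lengths[c] / total)))
                 for c in chroms}
    # fix rounding drift on the last chrom
    drift = config.n_regions - sum(per_chrom.values())
    per_chrom[chroms[-1]] += drift

    regions = []
    i = 0
    for chrom in chroms:
        k = per_chrom[chrom]
        clen = config.chrom_lengths[chrom]
        pitch = clen // k
        if pitch <= config.region_length:
            raise ValueError("too many regions for the genome size")
        for j in range(k):
            start = j * pitch + int(rng.integers(0, pitch - config.region_length))
            i += 1
            regions.append(GenomicInterval(chrom, start,
                                           start + config.region_length,
                                           name=f"region_{i:05d}"))

    n_planted = int(round(config.n_regions * config.planted_ts_fraction))
    planted_idx = rng.choice(config.n_regions, size=n_planted, replace=False)
    specific = np.array([""] * config.n_regions, dtype=object)
    for k, ridx in enumerate(planted_idx):
        specific[ridx] = config.tissues[k % config.n_tissues]

    samples = config.samples
    sample_tissue = config.sample_tissue
    lo, hi = config.sf_range
    sf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))
    mu = np.full((config.n_regions, len(samples)), config.base_lambda)
    for j, s in enumerate(samples):
        boost = specific == sample_tissue[s]
        mu[boost, j] *= config.planted_fc
        mu[:, j] *= sf[j]
    raw = pd.DataFrame(rng.poisson(mu),
                       index=[iv.name for iv in regions], columns=samples)
    matrix = RegionCountMatrix(regions=regions, raw=raw,
                               sample_tissue=sample_tissue,
                               size_factors=None)
    truth = pd.DataFrame({
        "region": [iv.name for iv in regions],
        "chrom": [iv.chrom for iv in regions],
        "start": [iv.start for iv in regions],
        "end": [iv.end for iv in regions],
        "specific_tissue": specific,
        "fold_change": np.where(specific == "", 1.0, config.planted_fc),
    })
    return matrix, truth


# ---------------------------------------------------------------- expression

def gen_expression_and_links(config: SimConfig, region_truth: pd.DataFrame,
                             gene_models, region_signal: pd.DataFrame | None = None,
                             window: int = 500_000):
    """Gene x tissue TPM table with planted region-gene links.

    Each planted region is linked to the nearest free gene TSS within the
    window: that gene's TPM across tissues is the region's normalized signal
    plus Gaussian noise scaled so the expected Pearson r equals ``link_r``
    (noise sd = sd(signal) * sqrt(1/r^2 - 1)). All other genes draw
    tissue-independent lognormal TPM. When the measured ``region_signal``
    (tissues as columns) is omitted, the expected signal implied by the truth
    table is used.

    Returns (tpm DataFrame, link truth DataFrame).
    """
    rng = config.rng(_EXPR)
    tissues = config.tissues
    if region_signal is None:
        base = config.base_lambda
        sig = {}
        for row in region_truth.itertuples(index=False):
            x = np.full(len(tissues), float(base))
            if row.specific_tissue:
                x[tissues.index(row.specific_tissue)] *= row.fold_change
            sig[row.region] = x
        region_signal = pd.DataFrame.from_dict(sig, orient="index",
                                               columns=tissues)

    genes_by_chrom: dict[str, list] = {}
    for g in gene_models:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    # unlinked genes: per-gene lognormal baseline, modest Gaussian tissue
    # noise (cv 0.15); a heavy-tailed per-tissue draw would manufacture
    # spurious high correlations against one-vs-rest spiky region signal
    baseline = rng.lognormal(mean=np.log(20.0), sigma=0.5,
                             size=(len(gene_models), 1))
    noise = rng.normal(1.0, 0.15, size=(len(gene_models), len(tissues)))
    tpm = pd.DataFrame(np.maximum(baseline * noise, 0.0),
                       index=[g.gene_id for g in gene_models], columns=tissues)

    used: set[str] = set()
    links = []
    planted = region_truth[region_truth["specific_tissue"] != ""]
    for row in planted.itertuples(index=False):
        iv = GenomicInterval(row.chrom, row.start, row.end, name=row.region)
        candidates = [(iv.distance_to_point(g.tss), g)
                      for g in genes_by_chrom.get(row.chrom, [])
                      if g.gene_id not in used
                      and iv.distance_to_point(g.tss) <= window]
        if not candidates:
            continue
        _, gene = min(candidates, key=lambda t: (t[0], t[1].gene_id))
        used.add(gene.gene_id)
        x = region_signal.loc[row.region, tissues].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        noise_sd = sd * np.sqrt(1.0 / config.link_r**2 - 1.0)
        y = x + rng.normal(0.0, noise_sd, size=len(tissues))
        tpm.loc[gene.gene_id] = np.maximum(y, 0.0)
        links.append({"region": row.region, "gene": gene.gene_id,
                      "tissue": row.specific_tissue})
    return tpm, pd.DataFrame(links, columns=["region", "gene", "tissue"])


# ---------------------------------------------------------------- SNPs

def planted_inside_probability(config: SimConfig, coverage: float) -> float:
    """P(planted-phenotype SNP falls in the target regions) giving the target OR.

    Background SNPs land inside with probability ``coverage`` (the fraction
    of the genome the regions cover); solving OR = odds_in / odds_bg for the
    planted phenotype gives the required inside-probability.
    """
    odds = config.planted_or * coverage / (1.0 - coverage)
    return odds / (1.0 + odds)


def gen_snp_catalog(config: SimConfig, region_truth: pd.DataFrame,
                    target_tissue: str | None = None):
    """SNP catalog with one phenotype planted inside a tissue's regions.

    Background phenotypes place SNPs uniformly on the genome; the planted
    phenotype's SNPs fall inside the target tissue's planted regions with
    the probability that makes the generative odds ratio ``planted_or``
    (against a uniform background over the same genome).

    Returns (snps DataFrame, truth dict).
    """
    rng = config.rng(_SNPS)
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    genome_bp = lengths.sum()

    planted = region_truth[region_truth["specific_tissue"] != ""]
    if target_tissue is None:
        target_tissue = config.tissues[0]
    target = planted[planted["specific_tissue"] == target_tissue]
    if target.empty:
        raise ValueError(f"no planted regions for tissue {target_tissue}")
    target_bp = float((target["end"] - target["start"]).sum())
    coverage = target_bp / genome_bp
    p_in = planted_inside_probability(config, coverage)
    # mixture weight for the "drop into a target region" branch: the uniform
    # branch already lands inside with probability `coverage`, so solve
    # q + (1 - q) * coverage = p_in
    q = max(0.0, (p_in - coverage) / (1.0 - coverage))

    per_pheno = config.n_snps // config.n_phenotypes
    phenotypes = [f"phenotype_{i + 1:02d}" for i in range(config.n_phenotypes - 1)]
    planted_phenotype = "phenotype_planted"

    def uniform_positions(n):
        chrom_idx = rng.choice(len(chroms), size=n, p=lengths / genome_bp)
        pos = np.array([rng.integers(0, lengths[i]) for i in chrom_idx])
        return [(chroms[i], int(p)) for i, p in zip(chrom_idx, pos)]

    rows, rsid = [], 0
    for pheno in phenotypes:
        seen = set()
        while len(seen) < per_pheno:
            for key in uniform_positions(per_pheno - len(seen)):
                seen.add(key)
        for chrom, pos in sorted(seen):
            rsid += 1
            rows.append((chrom, pos, f"rs{rsid:07d}", pheno))

    starts = target["start"].to_numpy()
    ends = target["end"].to_numpy()
    t_chroms = target["chrom"].to_numpy()
    seen = set()
    while len(seen) < per_pheno:
        need = per_pheno - len(seen)
        inside = rng.random(need) < q
        for flag in inside:
            if flag:
                j = rng.integers(0, len(starts))
                key = (t_chroms[j], int(rng.integers(starts[j], ends[j])))
            else:
                key = uniform_positions(1)[0]
            seen.add(key)
    for chrom, pos in sorted(seen):
        rsid += 1
        rows.append((chrom, pos, f"rs{rsid:07d}", planted_phenotype))

    snps = pd.DataFrame(rows, columns=["chrom", "pos", "rsid", "phenotype"])
    truth = {"phenotype": planted_phenotype, "tissue": target_tissue,
             "odds_ratio": config.planted_or, "inside_prob": p_in,
             "coverage": coverage}
    return snps, truth
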