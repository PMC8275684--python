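"""SNP-catalog enrichment in tsDhMRs via one-sided Fisher's exact test.

Each GWAS phenotype contributes a set of SNPs; the 2x2 table compares the
phenotype's SNPs against all other catalog SNPs (the universe), split by
membership in the tsDhMR interval set. Significance is the one-sided
(greater) Fisher exact p; the effect size is the sample odds ratio ad/bc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalIndex


@dataclass(frozen=True)
class EnrichmentResult:
    phenotype: str
    a: int  # phenotype SNPs inside tsDhMRs
    b: int  # phenotype SNPs outside
    c: int  # other SNPs inside
    d: int  # other SNPs outside
    odds_ratio: float
    p_value: float


def overlap_snps(snps: pd.DataFrame, regions) -> np.ndarray:
    """Boolean membership of each SNP position in the region set.

    SNP positions are 0-based points; regions are half-open, so a SNP at a
    region's start is inside and one at its end coordinate is outside. SNPs
    on chromosomes absent from the region set count as outside (warning).
    """
    index = IntervalIndex(list(regions))
    flags = np.zeros(len(snps), dtype=bool)
    region_chroms = set(index._starts)
    off = set(snps["chrom"].unique()) - region_chroms
    if off and region_chroms:
        warnings.warn(f"SNPs on chromosomes without regions: {sorted(off)}")
    chroms = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        flags[mask] = index.contains(chrom, pos[mask])
    return flags


def fisher_enrichment(snps: pd.DataFrame, regions,
                      adjust: bool = True) -> pd.DataFrame:
    """Per-phenotype one-sided (greater) Fisher test of tsDhMR overlap.

    The universe is every SNP in the catalog. A SNP present under several
    phenotypes is counted once per phenotype test. Returns a DataFrame with
    the 2x2 cells, sample odds ratio (inf when b*c = 0 with a*d > 0),
    p_value, and Benjamini-Hochberg adjusted p across phenotypes (a reported
    extra; the raw p is the primary statistic).
    """
    if snps.empty:
        raise ValueError("empty SNP catalog")
    inside = overlap_snps(snps, regions)
    n_in = int(inside.sum())
    n_all = len(snps)
    rows = []
    for phenotype, sub_idx in snps.groupby("phenotype").indices.items():
        a = int(inside[sub_idx].sum())
        b = len(sub_idx) - a
        c = n_in - a
        d = (n_all - len(sub_idx)) - c
        if b * c == 0:
            oddsr = np.inf if a * d > 0 else 0.0
        else:
            oddsr = (a * d) / (b * c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(EnrichmentResult(phenotype, a, b, c, d, float(oddsr),
                                     float(p)))
    out = pd.DataFrame([r.__dict__ for r in rows]).sort_values("p_value",
                                                               kind="stable")
    if adjust:
        out["p_bh"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out.reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(1.0, adj_sorted)
    return adj
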