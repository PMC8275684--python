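"""Tissue-specific differentially hydroxymethylated region (tsDhMR) calling.

Peaks from all samples are merged into a single region set; per-region read
counts are depth-normalized by median-of-ratios size factors, replicates of a
tissue are merged, and each (region, tissue) is tested one-vs-rest with a
one-tailed Poisson test whose rate is the mean of the other tissues. Regions
with Bonferroni-adjusted P < alpha and fold change > min_fc are tsDhMRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, merge_intervals
from .sites import bonferroni_adjust

merge_peaks = merge_intervals


@dataclass
class RegionCountMatrix:
    """Merged regions x samples raw counts with per-sample size factors."""

    regions: list[GenomicInterval]
    raw: pd.DataFrame                      # regions x samples, integer counts
    sample_tissue: dict[str, str]          # sample -> tissue label
    size_factors: pd.Series | None = None
    normalized: pd.DataFrame | None = field(default=None, repr=False)

    def normalize(self) -> "RegionCountMatrix":
        if self.size_factors is None:
            self.size_factors = size_factors(self.raw)
        self.normalized = self.raw / self.size_factors
        return self


def size_factors(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (per-sample sequencing-depth scalars).

    The reference for each region is the geometric mean of its counts across
    samples; regions with a zero in any sample are excluded from the
    reference. A sample's factor is the median over regions of its count
    divided by the reference.
    """
    counts = raw.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no region has positive counts in every sample; add a pseudocount "
            "or drop empty regions before normalization")
    kept = counts[all_positive]
    ref = np.exp(np.log(kept).mean(axis=1, keepdims=True))  # geometric mean
    factors = np.median(kept / ref, axis=0)
    return pd.Series(factors, index=raw.columns, name="size_factor")


def merge_replicates(normalized: pd.DataFrame, sample_tissue: dict,
                     mode: str = "mean") -> pd.DataFrame:
    """Aggregate normalized counts of a tissue's replicates (mean or sum)."""
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown replicate merge mode {mode!r}")
    unknown = [s for s in normalized.columns if s not in sample_tissue]
    if unknown:
        raise ValueError(f"samples with unknown tissue label: {unknown}")
    tissues = normalized.columns.map(sample_tissue)
    grouped = normalized.T.groupby(tissues)
    out = grouped.mean() if mode == "mean" else grouped.sum()
    return out.T


def poisson_upper_pvalue(count, lam, lambda_min: float = 0.5):
    """Upper-tail P(X >= count), X ~ Poisson(lambda). Vectorized.

    Non-integer counts (normalized values) are floored, which is conservative
    for an upper tail. A zero rate is replaced by ``lambda_min`` to avoid
    p = 0 artifacts when the other tissues are empty.
    """
    count = np.asarray(count, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(count < 0) or np.any(lam < 0):
        raise ValueError("count and lambda must be nonnegative")
    k = np.floor(count)
    lam_eff = np.maximum(lam, lambda_min)
    p = stats.poisson.sf(k - 1, lam_eff)
    return p if p.ndim else float(p)


def call_tsdhmrs(tissue_matrix: pd.DataFrame,
                 alpha: float = 0.05,
                 min_fc: float = 2.0,
                 family: str = "global",
                 lambda_min: float = 0.5) -> pd.DataFrame:
    """One-vs-rest Poisson test of every (region, tissue) pair.

    ``tissue_matrix`` is regions x tissues of replicate-merged normalized
    counts. For each pair, lambda is the mean of the other tissues' values;
    the Bonferroni family is all region x tissue tests (``family="global"``)
    or one tissue's tests (``family="per-tissue"``). A region may be specific
    to more than one tissue.

    Returns a long DataFrame with columns region, tissue, tissue_count,
    lambda_other, fold_change, p_raw, p_bonferroni, is_tsdhmr.
    """
    if tissue_matrix.shape[1] < 2:
        raise ValueError("tsDhMR calling requires at least two tissues")
    if family not in ("global", "per-tissue"):
        raise ValueError(f"unknown Bonferroni family {family!r}")
    values = tissue_matrix.to_numpy(dtype=float)
    n_regions, n_tissues = values.shape
    totals = values.sum(axis=1, keepdims=True)
    lam_other = (totals - values) / (n_tissues - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(lam_other > 0, values / lam_other,
                      np.where(values > 0, np.inf, 1.0))
    p_raw = poisson_upper_pvalue(values, lam_other, lambda_min=lambda_min)
    m = n_regions * n_tissues if family == "global" else n_regions
    p_adj = np.minimum(1.0, m * p_raw)

    long = pd.DataFrame({
        "region": np.repeat(tissue_matrix.index.to_numpy(), n_tissues),
        "tissue": np.tile(tissue_matrix.columns.to_numpy(), n_regions),
        "tissue_count": values.ravel(),
        "lambda_other": lam_other.ravel(),
        "fold_change": fc.ravel(),
        "p_raw": p_raw.ravel(),
        "p_bonferroni": p_adj.ravel(),
    })
    long["is_tsdhmr"] = (long["p_bonferroni"] < alpha) & (long["fold_change"] > min_fc)
    return long


def count_matrix_from_sites(site_counts: pd.DataFrame,
                            regions: list[GenomicInterval]) -> pd.DataFrame:
    """Total per-region NT counts per sample (region x sample raw matrix)."""
    names = [iv.name if iv.name != "." else f"region_{i}"
             for i, iv in enumerate(regions)]
    samples = sorted(site_counts["sample"].unique())
    out = pd.DataFrame(0, index=names, columns=samples, dtype=int)
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for name, iv in zip(names, regions):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, name))
    for (chrom, sample), sub in site_counts.groupby(["chrom", "sample"]):
        if chrom not in by_chrom:
            continue
        pos = sub["pos"].to_numpy()
        nt = sub["NT"].to_numpy()
        for start, end, name in by_chrom[chrom]:
            mask = (pos >= start) & (pos < end)
            if mask.any():
                out.loc[name, sample] += int(nt[mask].sum())
    return out
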