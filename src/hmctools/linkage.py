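"""Linking tissue-specific regions to putative target genes.

Tissue-specifically expressed genes are defined by fold change over the mean
of the other tissues (top 300 per tissue after a mean-TPM filter); gene-body
5hmC density is an RPKM-like quantity; tsDhMRs are linked to genes whose TSS
lies within a 500-kb window and whose expression correlates with the region's
normalized 5hmC signal across tissues (Pearson r > 0.8, P < 0.05).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300  # underflow cap for perfect correlations


def tissue_specific_genes(tpm: pd.DataFrame, top_n: int = 300,
                          min_mean_tpm: float = 1.0,
                          min_fc: float = 2.0) -> dict[str, pd.DataFrame]:
    """Per-tissue lists of tissue-specifically expressed genes.

    Genes with mean TPM below ``min_mean_tpm`` are dropped as globally low
    expressed. FC(gene, tissue) = TPM / mean TPM of the other tissues; per
    tissue, genes are ranked by descending FC, the top ``top_n`` taken, and
    genes with FC below ``min_fc`` removed from that list (rank-then-filter).
    """
    if tpm.shape[1] < 2:
        raise ValueError("need at least two tissues")
    expressed = tpm[tpm.mean(axis=1) >= min_mean_tpm]
    values = expressed.to_numpy(dtype=float)
    n_t = values.shape[1]
    other_mean = (values.sum(axis=1, keepdims=True) - values) / (n_t - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(other_mean > 0, values / other_mean,
                      np.where(values > 0, np.inf, 0.0))
    out = {}
    for j, tissue in enumerate(expressed.columns):
        df = pd.DataFrame({"gene": expressed.index, "tpm": values[:, j],
                           "fold_change": fc[:, j]})
        df = df.sort_values("fold_change", ascending=False, kind="stable")
        df = df.head(top_n)
        out[tissue] = df[df["fold_change"] >= min_fc].reset_index(drop=True)
    return out


def gene_body_signal(gene_counts: pd.DataFrame, gene_models,
                     library_sizes: pd.Series) -> pd.DataFrame:
    """RPKM-like 5hmC density: counts / (gene length kb x library size M).

    ``gene_counts`` is gene x sample raw counts over gene bodies. Invariant
    to jointly scaling counts and library sizes.
    """
    lengths = {}
    for g in gene_models:
        if g.length <= 0:
            raise ValueError(f"gene {g.gene_id}: zero-length body")
        lengths[g.gene_id] = g.length
    missing = [g for g in gene_counts.index if g not in lengths]
    if missing:
        raise ValueError(f"genes without models: {missing[:5]}")
    len_kb = pd.Series({g: lengths[g] / 1000 for g in gene_counts.index})
    lib_m = library_sizes.reindex(gene_counts.columns) / 1e6
    return gene_counts.div(len_kb, axis=0).div(lib_m, axis=1)


def expression_correlation(signal: pd.DataFrame, tpm: pd.DataFrame,
                           method: str = "spearman",
                           axis: str = "tissue") -> pd.Series:
    """Correlation between 5hmC signal and expression over matched labels.

    ``axis="tissue"``: one coefficient per tissue, across shared genes.
    ``axis="gene"``: one per gene, across shared tissues. Constant vectors
    yield NaN (undefined correlation).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    genes = signal.index.intersection(tpm.index)
    tissues = signal.columns.intersection(tpm.columns)
    if axis == "tissue":
        items, get = tissues, lambda k: (signal.loc[genes, k], tpm.loc[genes, k])
    elif axis == "gene":
        items, get = genes, lambda k: (signal.loc[k, tissues], tpm.loc[k, tissues])
    else:
        raise ValueError(f"unknown axis {axis!r}")
    corr_fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    out = {}
    for key in items:
        x, y = (v.to_numpy(dtype=float) for v in get(key))
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out[key] = np.nan
            continue
        out[key] = float(corr_fn(x, y)[0])
    return pd.Series(out, name=f"{method}_{axis}")


def pearson_link_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided t-test p-value (t = r sqrt(n-2)/sqrt(1-r^2)).

    Degenerate perfect fits report the underflow-capped minimum p.
    """
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return (1.0 if r > 0 else -1.0), P_FLOOR
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, max(float(p), P_FLOOR)


def link_tsdhmrs(tsdhmrs: pd.DataFrame, regions_by_name: dict, gene_models,
                 region_signal: pd.DataFrame, tpm: pd.DataFrame,
                 window: int = 500_000, min_r: float = 0.8,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Correlate tsDhMR 5hmC signal with expression of genes within a window.

    Candidate pairs are (region, gene) where the minimum distance from the
    region interval to the gene TSS is <= ``window`` (inclusive). For each
    pair, Pearson r across tissues between the region's replicate-merged
    normalized counts and the gene's TPM; the p-value comes from the t
    transform with n - 2 degrees of freedom, two-sided. Confident links have
    r > min_r, p < alpha and distance within the window.

    ``tsdhmrs`` is the call table from :func:`hmctools.regions.call_tsdhmrs`
    (only rows with is_tsdhmr are linked); ``regions_by_name`` maps region
    name -> GenomicInterval.
    """
    tissues = region_signal.columns.intersection(tpm.columns)
    if len(tissues) < 4:
        raise ValueError("linkage needs >= 4 tissues for the t-test")
    called = tsdhmrs[tsdhmrs["is_tsdhmr"]]
    genes_by_chrom: dict[str, list] = {}
    for g in gene_models:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for region_name in called["region"].unique():
        iv = regions_by_name[region_name]
        x = region_signal.loc[region_name, tissues].to_numpy(dtype=float)
        for g in genes_by_chrom.get(iv.chrom, []):
            dist = iv.distance_to_point(g.tss)
            if dist > window or g.gene_id not in tpm.index:
                continue
            y = tpm.loc[g.gene_id, tissues].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"constant series for pair ({region_name}, {g.gene_id}); "
                    "skipped")
                continue
            r, p = pearson_link_test(x, y)
            rows.append({"region": region_name, "gene": g.gene_id,
                         "distance": dist, "pearson_r": r, "p_value": p,
                         "confident": bool(r > min_r and p < alpha)})
    return pd.DataFrame(rows, columns=["region", "gene", "distance",
                                       "pearson_r", "p_value", "confident"])
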