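"""Single-base 5hmC site calling from C-to-T conversion counts.

The chemistry converts 5hmC-derived cytosines so they sequence as T. At a
true 5hmC site the conversion fraction NT/(NT+NC) is high (calibrated on a
fully hydroxymethylated spike-in cytosine); at an unmodified cytosine it sits
at a low background rate p_bg (calibrated on unmodified spike-in cytosines).
A site is tested against NT ~ Binomial(N, p_bg), the family-wise error rate
is controlled by Holm's step-down procedure, and calls are additionally gated
on membership in an enrichment peak of the same tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import IntervalIndex

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class ConversionRates:
    """Calibrated C-to-T conversion rates: p_true at 5hmC, p_bg at unmodified C."""

    p_true: float
    p_bg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bg < self.p_true <= 1.0):
            raise ValueError(
                f"require 0 <= p_bg < p_true <= 1, got p_bg={self.p_bg}, "
                f"p_true={self.p_true} (p_bg >= p_true signals failed chemistry)")


def estimate_conversion(spikeins: pd.DataFrame) -> ConversionRates:
    """Pooled conversion-rate estimates from spike-in counts.

    ``spikeins`` has columns site_id, state ("5hmC" or "unmodified"), NT, NC.
    Each rate is the pooled ratio sum(NT)/sum(NT+NC) over that class.
    """
    rates = {}
    for state in ("5hmC", "unmodified"):
        sub = spikeins[spikeins["state"] == state]
        depth = int(sub["NT"].sum() + sub["NC"].sum())
        if sub.empty or depth == 0:
            raise ValueError(f"no covered {state} spike-in sites for calibration")
        rates[state] = sub["NT"].sum() / depth
    return ConversionRates(p_true=rates["5hmC"], p_bg=rates["unmodified"])


def filter_reads(read_conversion_counts: dict, min_conversions: int = 1) -> list:
    """Keep read(-pair) ids whose C-to-T conversion count is >= min_conversions.

    Reads without conversion evidence cannot come from a 5hmC-containing
    fragment and only add background; min_conversions=0 is the identity filter.
    """
    kept = []
    for read_id, count in read_conversion_counts.items():
        if count < 0:
            raise ValueError(f"read {read_id}: negative conversion count {count}")
        if count >= min_conversions:
            kept.append(read_id)
    return kept


def binom_site_pvalue(nt, n, p_bg):
    """Upper-tail P(X >= NT), X ~ Binomial(N, p_bg). Vectorized.

    Computed via the regularized incomplete beta function (scipy's survival
    function), which evaluates the tail in log-stable form; values below
    1e-300 are reported as 0.
    """
    nt = np.asarray(nt)
    n = np.asarray(n)
    if np.any(nt < 0) or np.any(nt > n):
        raise ValueError("require 0 <= NT <= N")
    if not (0 < p_bg < 1):
        raise ValueError("require 0 < p_bg < 1")
    # P(X >= k) = sf(k - 1)
    p = stats.binom.sf(nt - 1, n, p_bg)
    p = np.where(p < 1e-300, 0.0, p)
    return p if p.ndim else float(p)


def holm_adjust(pvalues, family_size: int | None = None) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order.

    Sort ascending; adj(i) = min(1, max_{j<=i} (m - j + 1) * p_(j)); the
    running maximum enforces monotonicity. ``family_size`` lets the family m
    exceed the number of supplied p-values, for procedures where some family
    members were examined but not explicitly tested (their implicit p-values
    are large and never bind the step-down maximum).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if family_size is None else int(family_size)
    if m < p.size:
        raise ValueError("family_size smaller than the number of p-values")
    if p.size == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    factors = m - np.arange(p.size)
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(factors * p[order]))
    adj = np.empty(p.size)
    adj[order] = adj_sorted
    return adj


def bonferroni_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p); m defaults to len(pvalues)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, (m if m is not None else p.size) * p)


def classify_context(genome, chrom: str, pos: int, strand: str) -> tuple[str, str]:
    """Classify a cytosine as CG / CHG / CHH and report its immediate 3' base.

    ``genome`` maps chrom -> uppercase sequence. On the minus strand the
    classification runs on the reverse complement: the cytosine appears as G
    on the plus strand and its 3' neighbours lie at pos-1, pos-2.

    Returns (context, next_base). Raises if the position is not a cytosine on
    the requested strand or the 2-base context runs off the chromosome end.
    """
    seq = genome[chrom]
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"{chrom}:{pos}(+) is {seq[pos]!r}, not C")
        if pos + 1 >= len(seq):
            raise ValueError(f"{chrom}:{pos}(+): context truncated at chrom end")
        nxt = seq[pos + 1]
        if nxt == "G":
            return "CG", nxt
        if pos + 2 >= len(seq):
            raise ValueError(f"{chrom}:{pos}(+): context truncated at chrom end")
        return ("CHG" if seq[pos + 2] == "G" else "CHH"), nxt
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"{chrom}:{pos}(-) is {COMPLEMENT[seq[pos]]!r} "
                             "on the minus strand, not C")
        if pos - 1 < 0:
            raise ValueError(f"{chrom}:{pos}(-): context truncated at chrom end")
        nxt = COMPLEMENT[seq[pos - 1]]
        if nxt == "G":
            return "CG", nxt
        if pos - 2 < 0:
            raise ValueError(f"{chrom}:{pos}(-): context truncated at chrom end")
        return ("CHG" if COMPLEMENT[seq[pos - 2]] == "G" else "CHH"), nxt
    raise ValueError(f"invalid strand {strand!r}")


def call_sites(table: pd.DataFrame,
               rates: ConversionRates,
               peaks_by_tissue: dict | None = None,
               sample_tissue: dict | None = None,
               alpha: float = 0.001,
               min_depth: int = 5,
               min_nt: int = 3,
               family: str = "per-sample",
               family_members: str = "input") -> pd.DataFrame:
    """Call 5hmC sites per sample with Holm FWER control and peak gating.

    Sites with N < min_depth or NT < min_nt are discarded before testing and
    are never reported. The Holm family spans one sample
    (``family="per-sample"``, default) or one tissue's samples pooled
    (``family="per-tissue"``). By default the family *size* counts every site
    of that scope present in the input (``family_members="input"``): the
    coverage filter is data-dependent selection, and shrinking the family to
    the filter's survivors would not control the family-wise error rate over
    the sites examined. ``family_members="tested"`` restricts the family to
    filter-passing sites.

    ``peaks_by_tissue`` maps tissue -> interval list (the union of that
    tissue's replicate peaks); ``sample_tissue`` maps sample -> tissue. When
    peaks are omitted every site counts as in-peak.

    Returns the table restricted to tested sites with columns p_raw, p_adj,
    in_peak and called (called <=> p_adj < alpha and in_peak).
    """
    if rates is None:
        raise ValueError("conversion rates are required")
    if family not in ("per-sample", "per-tissue"):
        raise ValueError(f"unknown family scope {family!r}")
    if family_members not in ("input", "tested"):
        raise ValueError(f"unknown family_members {family_members!r}")
    df = table.copy()
    if "N" not in df.columns:
        df["N"] = df["NT"] + df["NC"]
    if sample_tissue is None:
        sample_tissue = {s: s for s in df["sample"].unique()}
    scope = (df["sample"] if family == "per-sample"
             else df["sample"].map(sample_tissue))
    family_sizes = scope.value_counts().to_dict()
    df = df[(df["N"] >= min_depth) & (df["NT"] >= min_nt)].copy()
    if df.empty:
        for col in ("p_raw", "p_adj"):
            df[col] = pd.Series(dtype=float)
        for col in ("in_peak", "called"):
            df[col] = pd.Series(dtype=bool)
        return df
    df["p_raw"] = binom_site_pvalue(df["NT"].to_numpy(), df["N"].to_numpy(),
                                    rates.p_bg)

    group_key = (df["sample"] if family == "per-sample"
                 else df["sample"].map(sample_tissue))
    df["p_adj"] = np.nan
    for key, sub in df.groupby(group_key):
        m = family_sizes[key] if family_members == "input" else len(sub)
        df.loc[sub.index, "p_adj"] = holm_adjust(sub["p_raw"].to_numpy(),
                                                 family_size=m)

    if peaks_by_tissue is None:
        df["in_peak"] = True
    else:
        indexes = {t: IntervalIndex(ivs) for t, ivs in peaks_by_tissue.items()}
        in_peak = np.zeros(len(df), dtype=bool)
        tissues = df["sample"].map(sample_tissue).to_numpy()
        chroms = df["chrom"].to_numpy()
        positions = df["pos"].to_numpy()
        for tissue in np.unique(tissues):
            idx = indexes.get(tissue)
            if idx is None:
                continue
            mask = tissues == tissue
            for chrom in np.unique(chroms[mask]):
                sel = mask & (chroms == chrom)
                in_peak[sel] = idx.contains(chrom, positions[sel])
        df["in_peak"] = in_peak
    df["called"] = (df["p_adj"] < alpha) & df["in_peak"]
    return df


def symmetry_fraction(called_sites: pd.DataFrame) -> float:
    """Fraction of called CpG dyads that are called on both strands.

    A dyad is a plus-strand C at x paired with the minus-strand C at x + 1.
    The denominator is dyads with at least one called strand; NaN when there
    are none.
    """
    mask = (called_sites["context"] == "CG") & called_sites["called"].astype(bool)
    cg = called_sites[mask]
    if cg.empty:
        return float("nan")
    plus = cg[cg["strand"] == "+"]
    minus = cg[cg["strand"] == "-"]
    # dyad key: position of the plus-strand C
    plus_keys = set(zip(plus["chrom"], plus["pos"]))
    minus_keys = set(zip(minus["chrom"], minus["pos"] - 1))
    both = len(plus_keys & minus_keys)
    any_called = len(plus_keys | minus_keys)
    return both / any_called


def ch_fraction(called_sites: pd.DataFrame, by: str | None = None,
                sample_tissue: dict | None = None):
    """Proportion of called sites in non-CpG (CHG + CHH) context.

    With ``by=None`` returns the pooled fraction (NaN if nothing is called);
    with ``by="sample"`` a per-sample Series, with ``by="tissue"`` a pooled
    per-tissue Series (requires ``sample_tissue``).
    """
    called = called_sites[called_sites["called"].astype(bool)]
    is_ch = called["context"].isin(["CHG", "CHH"])
    if by is None:
        return float("nan") if called.empty else float(is_ch.mean())
    if by == "sample":
        key = called["sample"]
    elif by == "tissue":
        if sample_tissue is None:
            raise ValueError("by='tissue' requires sample_tissue")
        key = called["sample"].map(sample_tissue)
    else:
        raise ValueError(f"unknown grouping {by!r}")
    return is_ch.groupby(key).mean()
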