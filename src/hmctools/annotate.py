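"""Genomic feature annotation of sites and peaks.

Gene models induce four feature classes — promoter, exon, intron, intergenic —
that partition the genome after precedence flattening (promoter > exon >
intron > intergenic). Queries are assigned a single class; peak intervals are
classified at their midpoint. Enrichment per class is log2 of the observed
query fraction over the genomic background fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval, IntervalIndex, merge_intervals

CLASSES = ("promoter", "exon", "intron", "intergenic")


@dataclass
class FeatureCatalog:
    """Flattened, precedence-resolved feature classes covering the genome."""

    chrom_lengths: dict[str, int]
    promoter_halfwidth: int
    index: dict[str, IntervalIndex]        # class -> point index (flattened)
    lengths: dict[str, int]                # class -> flattened bp

    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())


def build_features(gene_models, chrom_lengths: dict[str, int],
                   promoter_halfwidth: int = 2000) -> FeatureCatalog:
    """Derive promoter/exon/intron/intergenic classes from gene models.

    Promoters are TSS +/- halfwidth (clipped at chromosome ends with a
    warning); exons come from the gene models (whole body if a model has no
    exon list); introns are the remainder of gene bodies; intergenic is the
    complement. Precedence promoter > exon > intron resolves overlaps, so the
    classes partition the genome.
    """
    promoters, exons, bodies = [], [], []
    for g in gene_models:
        if g.chrom not in chrom_lengths:
            raise ValueError(f"gene {g.gene_id}: unknown chrom {g.chrom}")
        clen = chrom_lengths[g.chrom]
        if g.end > clen:
            raise ValueError(f"gene {g.gene_id}: extends past chrom end")
        lo = g.tss - promoter_halfwidth
        hi = g.tss + promoter_halfwidth
        if lo < 0 or hi > clen:
            warnings.warn(f"promoter of {g.gene_id} clipped at chrom boundary")
            lo, hi = max(0, lo), min(clen, hi)
        promoters.append(GenomicInterval(g.chrom, lo, hi))
        bodies.append(GenomicInterval(g.chrom, g.start, g.end))
        exon_list = g.exons if g.exons else ((g.start, g.end),)
        for s, e in exon_list:
            exons.append(GenomicInterval(g.chrom, s, e))

    prom_idx = IntervalIndex(promoters)
    exon_idx = IntervalIndex(exons)
    body_idx = IntervalIndex(bodies)

    # flattened bp per class via precedence, computed by sweeping breakpoints
    lengths = dict.fromkeys(CLASSES, 0)
    pieces = {"promoter": merge_intervals(promoters) if promoters else [],
              "exon": merge_intervals(exons) if exons else [],
              "body": merge_intervals(bodies) if bodies else []}
    for chrom, clen in chrom_lengths.items():
        cuts = {0, clen}
        for ivs in pieces.values():
            for iv in ivs:
                if iv.chrom == chrom:
                    cuts.update((min(iv.start, clen), min(iv.end, clen)))
        cuts = sorted(cuts)
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            cls = _classify_point(chrom, lo, prom_idx, exon_idx, body_idx)
            lengths[cls] += hi - lo

    index = {
        "promoter": prom_idx,
        "exon": exon_idx,
        "intron": body_idx,    # intron = body minus promoter/exon via precedence
        "intergenic": None,
    }
    return FeatureCatalog(chrom_lengths=dict(chrom_lengths),
                          promoter_halfwidth=promoter_halfwidth,
                          index=index, lengths=lengths)


def _classify_point(chrom, pos, prom_idx, exon_idx, body_idx) -> str:
    if prom_idx.contains_point(chrom, pos):
        return "promoter"
    if exon_idx.contains_point(chrom, pos):
        return "exon"
    if body_idx.contains_point(chrom, pos):
        return "intron"
    return "intergenic"


def assign_class(query, catalog: FeatureCatalog) -> str:
    """Single feature class for a site (chrom, pos) or interval (midpoint)."""
    if isinstance(query, GenomicInterval):
        chrom, pos = query.chrom, query.midpoint
    else:
        chrom, pos = query
    if chrom not in catalog.chrom_lengths or not (
            0 <= pos < catalog.chrom_lengths[chrom]):
        raise ValueError(f"query {chrom}:{pos} outside the genome")
    return _classify_point(chrom, pos, catalog.index["promoter"],
                           catalog.index["exon"], catalog.index["intron"])


def assign_classes(chrom: str, positions, catalog: FeatureCatalog) -> np.ndarray:
    """Vectorized :func:`assign_class` for many positions on one chromosome."""
    positions = np.asarray(positions)
    if chrom not in catalog.chrom_lengths:
        raise ValueError(f"unknown chrom {chrom}")
    if np.any((positions < 0) | (positions >= catalog.chrom_lengths[chrom])):
        raise ValueError("positions outside the genome")
    out = np.full(positions.shape, "intergenic", dtype=object)
    in_body = catalog.index["intron"].contains(chrom, positions)
    out[in_body] = "intron"
    out[catalog.index["exon"].contains(chrom, positions)] = "exon"
    out[catalog.index["promoter"].contains(chrom, positions)] = "promoter"
    return out


def class_enrichment(assignments, catalog: FeatureCatalog) -> dict[str, float]:
    """log2(observed/expected) per feature class.

    observed = fraction of queries assigned to the class; expected = fraction
    of genome bp the class covers. Classes with no observations map to -inf.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("need at least one assignment")
    n = len(assignments)
    genome = catalog.genome_length()
    out = {}
    for cls in CLASSES:
        obs = sum(a == cls for a in assignments) / n
        exp = catalog.lengths[cls] / genome
        if exp == 0:
            if obs > 0:
                raise ValueError(
                    f"class {cls} observed but covers no genome (catalog "
                    "inconsistency)")
            continue
        out[cls] = float(np.log2(obs / exp)) if obs > 0 else float("-inf")
    return out
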