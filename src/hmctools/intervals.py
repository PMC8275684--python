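"""Genomic intervals and the handful of interval operations the pipeline needs.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Converting to 1-based display coordinates adds exactly 1 to ``start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional BED-style annotations.

    ``extra`` preserves any BED columns beyond the canonical six verbatim,
    so narrowPeak inputs round-trip without interpreting summit columns.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    extra: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def distance_to_point(self, pos: int) -> int:
        """Minimum gap from this interval to a point; 0 if the point is inside."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


@dataclass(frozen=True)
class GeneModel:
    """A minimal gene model: full span, strand-aware TSS and optional exons.

    The TSS is ``start`` on the + strand and ``end - 1`` on the - strand.
    When ``exons`` is empty the whole gene body is treated as exonic.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               name=self.gene_id, strand=self.strand)


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Union of overlapping-or-touching intervals, per chromosome, sorted.

    Idempotent; names/scores of inputs are dropped (merged regions are new
    entities and get positional names downstream).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # touching intervals merge
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


class IntervalIndex:
    """Point-membership queries against a set of intervals via searchsorted.

    Intervals are merged internally, so membership is well defined even for
    overlapping inputs. Half-open: start inclusive, end exclusive.
    """

    def __init__(self, intervals):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for iv in merge_intervals(intervals) if intervals else []:
            self._starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[attr-defined]
            self._ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[attr-defined]
        for chrom in self._starts:
            self._starts[chrom] = np.asarray(self._starts[chrom])
            self._ends[chrom] = np.asarray(self._ends[chrom])

    def contains(self, chrom, pos) -> np.ndarray:
        """Vectorized membership for positions on one chromosome."""
        pos = np.atleast_1d(np.asarray(pos))
        if chrom not in self._starts:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(self._starts[chrom], pos, side="right") - 1
        inside = idx >= 0
        inside[inside] = pos[inside] < self._ends[chrom][idx[inside]]
        return inside

    def contains_point(self, chrom: str, pos: int) -> bool:
        return bool(self.contains(chrom, pos)[0])

    def total_length(self) -> int:
        return int(sum((e - s).sum() for s, e in
                       zip(self._starts.values(), self._ends.values())))
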