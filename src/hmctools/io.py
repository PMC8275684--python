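"""Readers and writers for the on-disk formats the pipeline consumes and emits.

Tabular formats are plain TSV with a header row; intervals are BED6 with any
extra columns (e.g. narrowPeak summits) preserved verbatim. Every reader/writer
pair round-trips valid inputs exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "sample", "NT", "NC"]
SNP_COLUMNS = ["chrom", "pos", "rsid", "phenotype"]
SPIKEIN_COLUMNS = ["site_id", "state", "NT", "NC"]
GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end",
                "exon_starts", "exon_ends", "biotype"]


class FormatError(ValueError):
    """Raised on malformed input files; carries the offending line when known."""


# ---------------------------------------------------------------- BED

def read_bed(path) -> list[GenomicInterval]:
    """Parse a BED file (3+ columns) into sorted GenomicIntervals.

    Columns beyond the sixth are preserved in ``extra``. Raises FormatError
    with a 1-based line number on malformed lines.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = GenomicInterval(chrom, start, end, name=name, score=score,
                                     strand=strand, extra=tuple(fields[6:]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            intervals.append(iv)
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def write_bed(intervals, path) -> None:
    """Write intervals as BED6(+extras), sorted by (chrom, start)."""
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)):
            score = f"{iv.score:g}"
            fields = [iv.chrom, str(iv.start), str(iv.end), iv.name, score, iv.strand]
            fields.extend(str(x) for x in iv.extra)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------- TSV tables

def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def _check_counts_nonnegative(df: pd.DataFrame, cols, path) -> None:
    for col in cols:
        if (df[col] < 0).any():
            raise FormatError(f"{path}: negative values in column {col!r}")


def read_site_counts(path) -> pd.DataFrame:
    """Per-cytosine converted (NT) / unconverted (NC) counts per sample.

    Keyed by (chrom, pos, strand, sample); duplicates rejected. A derived
    depth column ``N = NT + NC`` is added.
    """
    df = _read_tsv(path, SITE_COLUMNS)
    _check_counts_nonnegative(df, ["NT", "NC"], path)
    key = ["chrom", "pos", "strand", "sample"]
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key, keep=False)].iloc[0]
        raise FormatError(
            f"{path}: duplicate site row {dup.chrom}:{dup.pos}({dup.strand}) "
            f"sample {dup['sample']}")
    df = df.copy()
    df["N"] = df["NT"] + df["NC"]
    return df


def write_site_counts(df: pd.DataFrame, path) -> None:
    df[SITE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_tpm(path) -> pd.DataFrame:
    """Gene x tissue TPM matrix; first column is the gene id (index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative TPM values")
    return df


def write_tpm(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_snps(path) -> pd.DataFrame:
    """SNP catalog: chrom, pos (0-based), rsid, phenotype."""
    df = _read_tsv(path, SNP_COLUMNS)
    _check_counts_nonnegative(df, ["pos"], path)
    key = ["chrom", "pos", "phenotype"]
    if df.duplicated(subset=key).any():
        raise FormatError(f"{path}: duplicate (chrom,pos,phenotype) rows")
    return df


def write_snps(df: pd.DataFrame, path) -> None:
    df[SNP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_spikeins(path) -> pd.DataFrame:
    """Spike-in calibration counts: site_id, state in {5hmC, unmodified}, NT, NC."""
    df = _read_tsv(path, SPIKEIN_COLUMNS)
    _check_counts_nonnegative(df, ["NT", "NC"], path)
    bad = set(df["state"]) - {"5hmC", "unmodified"}
    if bad:
        raise FormatError(f"{path}: unknown spike-in states {sorted(bad)}")
    return df


def write_spikeins(df: pd.DataFrame, path) -> None:
    df[SPIKEIN_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- gene models

def _fmt_intlist(values) -> str:
    return ",".join(str(v) for v in values) if len(values) else "."


def _parse_intlist(text: str) -> tuple:
    if text in (".", "", None) or (isinstance(text, float) and np.isnan(text)):
        return ()
    return tuple(int(x) for x in str(text).split(","))


def write_gene_models(genes, path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
            "start": g.start, "end": g.end,
            "exon_starts": _fmt_intlist([s for s, _ in g.exons]),
            "exon_ends": _fmt_intlist([e for _, e in g.exons]),
            "biotype": g.biotype,
        })
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> list[GeneModel]:
    df = _read_tsv(path, GENE_COLUMNS)
    genes = []
    for row in df.itertuples(index=False):
        starts = _parse_intlist(row.exon_starts)
        ends = _parse_intlist(row.exon_ends)
        if len(starts) != len(ends):
            raise FormatError(f"{path}: gene {row.gene_id}: exon list length mismatch")
        genes.append(GeneModel(row.gene_id, row.chrom, row.strand,
                               int(row.start), int(row.end),
                               exons=tuple(zip(starts, ends)),
                               biotype=row.biotype))
    return genes


# ---------------------------------------------------------------- matrices

def write_count_matrix(df: pd.DataFrame, path) -> None:
    """Region x sample count matrix; the index holds region names."""
    df.to_csv(path, sep="\t", index_label="region")


def read_count_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
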