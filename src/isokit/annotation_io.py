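"""Readers and writers for the standard formats the pipeline touches.

GTF is 1-based inclusive on disk and converted to the internal 0-based
half-open convention at this boundary; BED needs no conversion.  The GTF
attribute column follows the GENCODE dialect (``key "value";``) and quote
characters inside values are backslash-escaped so that round-trips are
lossless.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .models import (
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    SequenceStore,
    TranscriptModel,
    ValidationError,
)

__all__ = [
    "read_gtf",
    "read_reference_gtf",
    "write_gtf",
    "read_counts",
    "read_bed",
    "read_fasta",
    "read_group_table",
    "GtfParseError",
]


class GtfParseError(ValueError):
    pass


_ATTR_RE = re.compile(r'(\w+)\s+"((?:[^"\\]|\\.)*)"\s*;')


def _parse_attributes(field: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for m in _ATTR_RE.finditer(field):
        key, raw = m.group(1), m.group(2)
        attrs[key] = raw.replace('\\"', '"').replace("\\\\", "\\")
    if not attrs and field.strip() not in ("", "."):
        raise GtfParseError(f"line {lineno}: unparseable attribute field {field!r}")
    return attrs


def _format_attributes(attrs: Mapping[str, str]) -> str:
    parts = []
    for key, value in attrs.items():
        escaped = str(value).replace("\\", "\\\\").replace('"', '\\"')
        parts.append(f'{key} "{escaped}";')
    return " ".join(parts)


def _scan_gtf(path: str | Path):
    """Yield (lineno, chrom, source, feature, start0, end, strand, attrs)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, source, feature, start, end, _score, strand, _frame, attr = fields
            try:
                start0, end1 = int(start) - 1, int(end)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: bad coordinates") from exc
            if end1 <= start0:
                raise ValidationError(
                    f"line {lineno}: feature end {end} < start {start}"
                )
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
            yield lineno, chrom, source, feature, start0, end1, strand, _parse_attributes(attr, lineno)


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read query transcript models from a GTF file.

    Only ``exon`` features are used; exons are grouped by transcript_id and
    sorted in genomic order.  Transcripts with exons on multiple
    chromosomes or strands are rejected.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str | None] = {}
    order: list[str] = []
    for lineno, chrom, _src, feature, s, e, strand, attrs in _scan_gtf(path):
        if feature != "exon":
            continue
        tid = attrs.get("transcript_id")
        if tid is None:
            raise GtfParseError(f"line {lineno}: exon without transcript_id")
        if tid not in exons:
            exons[tid] = []
            order.append(tid)
            gene_of[tid] = attrs.get("gene_id")
        exons[tid].append(GenomicInterval(chrom, s, e, strand))
    out = []
    for tid in order:
        ivs = exons[tid]
        if len({(iv.chrom, iv.strand) for iv in ivs}) > 1:
            raise ValidationError(
                f"transcript {tid}: exons on multiple chromosomes/strands"
            )
        out.append(
            TranscriptModel(tid, gene_of[tid], ivs[0].chrom, ivs[0].strand, ivs)
        )
    return out


def read_reference_gtf(
    path: str | Path, lncRNA_genes: Iterable[str] | None = None
) -> GenomeAnnotation:
    """Read a reference annotation and build its gene/site/chain indexes.

    ``gene`` feature lines are optional: when absent the gene extent is the
    union span of its transcripts.  ``lncRNA_genes`` is an optional list of
    gene ids to flag as long non-coding (biotype-to-flag mapping is left to
    the caller, so any GENCODE gene_type subset can be supplied).
    """
    transcripts = read_gtf(path)
    extents: dict[str, tuple[str, str, int, int]] = {}
    names: dict[str, str] = {}
    for lineno, chrom, _src, feature, s, e, strand, attrs in _scan_gtf(path):
        if feature == "gene" and "gene_id" in attrs:
            extents[attrs["gene_id"]] = (chrom, strand, s, e)
            if "gene_name" in attrs:
                names[attrs["gene_id"]] = attrs["gene_name"]
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        if t.gene_id is None:
            raise ValidationError(
                f"reference transcript {t.transcript_id} lacks gene_id"
            )
        by_gene.setdefault(t.gene_id, []).append(t)
    lnc = set(lncRNA_genes or ())
    genes = []
    for gid, ts in by_gene.items():
        if gid in extents:
            chrom, strand, s, e = extents[gid]
        else:
            chrom, strand = ts[0].chrom, ts[0].strand
            s, e = min(t.start for t in ts), max(t.end for t in ts)
        genes.append(
            Gene(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                start=s,
                end=e,
                transcripts=ts,
                is_lncRNA=gid in lnc,
                gene_name=names.get(gid),
            )
        )
    return GenomeAnnotation(genes)


def write_gtf(
    transcripts: Sequence[TranscriptModel],
    path: str | Path,
    annotations: Mapping[str, Mapping[str, str]] | None = None,
    source: str = "isokit",
) -> None:
    """Write transcripts as GENCODE-dialect GTF (transcript + exon lines).

    ``annotations`` optionally supplies extra attributes per transcript id
    (e.g. the structural category).
    """
    annotations = annotations or {}
    with open(path, "w") as fh:
        fh.write("##provider: isokit\n")
        for t in transcripts:
            attrs: dict[str, str] = {
                "gene_id": t.gene_id if t.gene_id is not None else t.transcript_id,
                "transcript_id": t.transcript_id,
            }
            attrs.update(annotations.get(t.transcript_id, {}))
            attr_str = _format_attributes(attrs)
            iv = t.interval
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{t.strand}\t.\t{attr_str}\n"
            )
            for e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attr_str}\n"
                )


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a full-length read-count table (TSV, transcripts x samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate transcript rows: {dupes}")
    if df.columns.duplicated().any():
        raise ValidationError("duplicate sample columns")
    if (df.values < 0).any():
        raise ValidationError("negative counts present")
    return df


def read_group_table(path: str | Path) -> pd.Series:
    """Read sample_id<TAB>group table; returns sample -> group mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"])
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in group table")
    return df.set_index("sample_id")["group"]


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (>=3 columns, 0-based half-open) peaks/intervals.

    Strand is taken from column 6 when present, else '+'.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"line {lineno}: BED line with < 3 fields")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
            peaks.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return peaks


def read_fasta(path: str | Path) -> SequenceStore:
    """Read a genome FASTA into an in-memory SequenceStore."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValidationError(f"duplicate FASTA header {record.id}")
        seqs[record.id] = str(record.seq)
    return SequenceStore(seqs)


def read_polya_motifs(path: str | Path) -> list[str]:
    """Read a plain-text polyA motif list (one uppercase DNA motif per line)."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            m = line.strip().upper()
            if not m:
                continue
            if set(m) - set("ACGT"):
                raise ValidationError(f"motif {m!r} not over alphabet ACGT")
            motifs.append(m)
    return motifs
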