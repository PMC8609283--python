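"""Core genomic domain model.

All coordinates are 0-based half-open on the genomic forward strand.
Splice junctions are stored as (donor, acceptor) pairs of genomic
coordinates ordered in *transcription* order: the donor is the intron
boundary adjacent to the upstream exon on the transcript's strand, so on
the minus strand the donor coordinate is numerically larger than the
acceptor and the junction list runs right-to-left along the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import reverse_complement

STRANDS = ("+", "-")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


Junction = tuple[int, int]  # (donor, acceptor), transcription order


@dataclass
class TranscriptModel:
    """One transcript model: ordered exons plus the derived junction chain.

    ``exons`` are kept in ascending genomic order; ``junctions`` (derived)
    are in transcription order, see module docstring.
    """

    transcript_id: str
    gene_id: str | None
    chrom: str
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        exons = sorted(self.exons, key=lambda e: e.start)
        for e in exons:
            if e.chrom != self.chrom or e.strand != self.strand:
                raise ValidationError(
                    f"{self.transcript_id}: exons on multiple chromosomes/strands"
                )
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons

    # -- derived geometry -------------------------------------------------

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic-order intron intervals [end_i, start_{i+1})."""
        return [
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def junctions(self) -> list[Junction]:
        """(donor, acceptor) pairs in transcription order."""
        introns = self.introns
        if self.strand == "+":
            return [(s, e) for s, e in introns]
        return [(e, s) for s, e in reversed(introns)]

    @property
    def chain(self) -> tuple[Junction, ...]:
        """Hashable junction-chain key (exact coordinates, no tolerance)."""
        return tuple(self.junctions)

    @property
    def tss(self) -> int:
        """First transcribed base: leftmost coordinate on +, rightmost on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Last transcribed base (3' terminus)."""
        return self.end - 1 if self.strand == "+" else self.start

    def exons_transcription_order(self) -> list[GenomicInterval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def junction_transcript_positions(self) -> list[int]:
        """Transcript coordinate of each junction, transcription order.

        The position of junction *i* is the cumulative length of the first
        i+1 exons, i.e. the transcript coordinate of the first base of the
        downstream exon.
        """
        pos, out = 0, []
        for exon in self.exons_transcription_order()[:-1]:
            pos += len(exon)
            out.append(pos)
        return out


@dataclass
class Gene:
    """A reference gene: extent, biotype flag and member transcripts."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)
    is_lncRNA: bool = False
    gene_name: str | None = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def donor_sites(self) -> frozenset[int]:
        return frozenset(d for t in self.transcripts for d, _ in t.junctions)

    @property
    def acceptor_sites(self) -> frozenset[int]:
        return frozenset(a for t in self.transcripts for _, a in t.junctions)

    def exon_intervals(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts for e in t.exons]

    def intron_intervals(self) -> list[tuple[int, int]]:
        return [iv for t in self.transcripts for iv in t.introns]


class GenomeAnnotation:
    """Reference annotation with per-gene splice-site and chain indexes.

    ``chain_index`` maps the exact junction-chain key of every multi-exonic
    reference transcript to the ids of the transcripts carrying it.
    """

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        self.transcripts: dict[str, TranscriptModel] = {}
        self.chain_index: dict[tuple, list[str]] = {}
        self._by_chrom: dict[str, list[Gene]] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise ValidationError(f"duplicate gene id {gene.gene_id}")
            self.genes[gene.gene_id] = gene
            self._by_chrom.setdefault(gene.chrom, []).append(gene)
            for t in gene.transcripts:
                if t.transcript_id in self.transcripts:
                    raise ValidationError(
                        f"duplicate transcript id {t.transcript_id}"
                    )
                self.transcripts[t.transcript_id] = t
                if not t.is_monoexonic:
                    self.chain_index.setdefault(
                        (t.chrom, t.strand) + t.chain, []
                    ).append(t.transcript_id)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: g.start)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    def gene_of(self, transcript_id: str) -> Gene:
        t = self.transcripts[transcript_id]
        return self.genes[t.gene_id]

    def chain_matches(self, t: TranscriptModel) -> list[str]:
        """Reference transcript ids whose chain equals t's chain exactly."""
        return self.chain_index.get((t.chrom, t.strand) + t.chain, [])

    def __len__(self) -> int:
        return len(self.genes)


class SequenceStore:
    """In-memory genome: chrom -> DNA string with checked substring access."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValidationError(
                f"[{start}, {end}) outside {chrom} (length {len(seq)})"
            )
        return seq[start:end]

    def fetch_clipped(self, chrom: str, start: int, end: int) -> str:
        """Like fetch but truncates the window at chromosome bounds."""
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        seq = self._seqs[chrom]
        return seq[max(0, start):min(len(seq), end)]

    def fetch_strand(self, chrom: str, start: int, end: int, strand: str) -> str:
        seq = self.fetch(chrom, start, end)
        return seq if strand == "+" else reverse_complement(seq)


def transcript_sequence(t: TranscriptModel, genome: SequenceStore) -> str:
    """Spliced transcript sequence in transcription order.

    Exon substrings are concatenated in genomic order and the whole string
    reverse-complemented when the transcript is on the minus strand.
    """
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom!r} absent from genome")
    seq = "".join(genome.fetch(t.chrom, e.start, e.end) for e in t.exons)
    return seq if t.strand == "+" else reverse_complement(seq)
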