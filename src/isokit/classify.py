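"""Structural classification of query transcript models against a reference.

Every query transcript receives exactly one category out of

    FSM, ISM, fusion, NIC, NNC, genic_genomic, genic_intron,
    antisense, intergenic

following the splice-junction-chain comparison used for long-read
transcript annotation: an FSM (full splice match) reproduces a reference
transcript's junction chain exactly, an ISM (incomplete splice match) is a
contiguous sub-chain of one, a NIC (novel in catalog) combines only
annotated donor/acceptor sites into a new chain, and an NNC (novel not in
catalog) uses at least one unannotated splice site.  Fusion transcripts
span two or more mutually non-overlapping gene loci.  Matching is exact:
no wobble tolerance is applied anywhere except the 3' tolerance of the
fragment filter.

The module also houses the artifact filters (5'-degradation fragments and
intrapriming) and the CAGE/polyA evidence annotators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .models import (
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    SequenceStore,
    TranscriptModel,
    transcript_sequence,
)

CATEGORIES = (
    "FSM",
    "ISM",
    "NIC",
    "NNC",
    "fusion",
    "antisense",
    "intergenic",
    "genic_genomic",
    "genic_intron",
)

#: categories grouped as "known" in summary tables
KNOWN_CATEGORIES = ("FSM", "ISM")

DEFAULT_INTRAPRIMING_WINDOW = 20
DEFAULT_INTRAPRIMING_RATE = 0.6
DEFAULT_POLYA_WINDOW = 50
DEFAULT_CAGE_WINDOW = 50
DEFAULT_FRAGMENT_3PRIME_TOL = 100


@dataclass
class ClassificationRecord:
    transcript_id: str
    category: str
    associated_genes: list[str] = field(default_factory=list)
    associated_transcript: str = "novel"
    length: int = 0
    n_exons: int = 0
    ir_flag: bool = False
    ir_introns: list[tuple[int, int]] = field(default_factory=list)
    ism_subtype: str | None = None  # 5prime / 3prime / internal
    dist_to_cage: int | None = None
    within_cage_50: bool | None = None
    polya_motif: str | None = None
    polya_dist: int | None = None
    frac_A_downstream: float | None = None
    intrapriming_flag: bool | None = None
    lncRNA_flag: bool = False

    @property
    def novel_flag(self) -> bool:
        return self.category not in KNOWN_CATEGORIES


# ---------------------------------------------------------------------------
# helpers


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _exonic_overlap(t: TranscriptModel, gene: Gene) -> bool:
    for e in t.exons:
        for ge in gene.exon_intervals():
            if _overlap(e.start, e.end, ge.start, ge.end):
                return True
    return False


def candidate_genes(t: TranscriptModel, ref: GenomeAnnotation) -> list[Gene]:
    """Same-strand genes with >=1 bp of exonic overlap with t, 5'->3' order."""
    hits = []
    for gene in ref.genes_on(t.chrom):
        if gene.strand != t.strand:
            continue
        if not _overlap(t.start, t.end, gene.start, gene.end):
            continue
        if _exonic_overlap(t, gene):
            hits.append(gene)
    hits.sort(key=lambda g: g.start, reverse=(t.strand == "-"))
    return hits


def _is_contiguous_subchain(sub: tuple, full: tuple) -> int | None:
    """Return the anchor offset if ``sub`` is a contiguous sub-chain of
    ``full`` (proper, i.e. shorter), else None."""
    n, m = len(sub), len(full)
    if n == 0 or n >= m:
        return None
    for i in range(m - n + 1):
        if full[i : i + n] == sub:
            return i
    return None


def _end_distance(t: TranscriptModel, r: TranscriptModel) -> int:
    return abs(t.tss - r.tss) + abs(t.tts - r.tts)


def _best_reference(
    t: TranscriptModel, matches: Sequence[TranscriptModel]
) -> TranscriptModel:
    """Tie-break multiple matching reference transcripts: minimal
    |dTSS| + |dTTS|, then lexicographic id (determinism)."""
    return min(matches, key=lambda r: (_end_distance(t, r), r.transcript_id))


def _retained_introns(
    t: TranscriptModel, genes: Sequence[Gene]
) -> list[tuple[int, int]]:
    """Annotated introns of the associated genes strictly contained in an
    exon of t (both intron boundaries inside the exon)."""
    retained = set()
    for gene in genes:
        for s, e in set(gene.intron_intervals()):
            for exon in t.exons:
                if exon.start < s and e < exon.end:
                    retained.add((s, e))
                    break
    return sorted(retained)


# ---------------------------------------------------------------------------
# the decision procedure


def classify_transcript(
    t: TranscriptModel, ref: GenomeAnnotation
) -> ClassificationRecord:
    """Assign one structural category to a query transcript.

    The steps are applied in precedence order FSM > ISM > fusion > NIC >
    NNC > genic_genomic > genic_intron > antisense > intergenic so the
    categories are disjoint and exhaustive.
    """
    rec = ClassificationRecord(
        transcript_id=t.transcript_id,
        category="intergenic",
        length=t.length,
        n_exons=t.n_exons,
    )
    genes = candidate_genes(t, ref)
    gene_ids = [g.gene_id for g in genes]

    if t.is_monoexonic:
        # FSM for mono-exonic queries: contained in a mono-exonic
        # reference transcript of an overlapping gene (tolerance 0).
        mono_matches = [
            r
            for g in genes
            for r in g.transcripts
            if r.is_monoexonic
            and r.start <= t.start
            and t.end <= r.end
        ]
        if mono_matches:
            best = _best_reference(t, mono_matches)
            rec.category = "FSM"
            rec.associated_genes = [ref.transcripts[best.transcript_id].gene_id]
            rec.associated_transcript = best.transcript_id
            return rec
        return _classify_nonspliced_overlap(t, ref, genes, gene_ids, rec)

    chain = t.chain

    # (2) FSM: exact chain equality
    fsm_ids = ref.chain_matches(t)
    if fsm_ids:
        best = _best_reference(t, [ref.transcripts[i] for i in fsm_ids])
        rec.category = "FSM"
        rec.associated_genes = [best.gene_id]
        rec.associated_transcript = best.transcript_id
        rec.ir_introns = _retained_introns(t, [ref.genes[best.gene_id]])
        rec.ir_flag = bool(rec.ir_introns)
        return rec

    # (3) ISM: contiguous sub-chain of some reference chain
    ism_matches = []
    for gene in genes:
        for r in gene.transcripts:
            if r.is_monoexonic:
                continue
            offset = _is_contiguous_subchain(chain, r.chain)
            if offset is not None:
                ism_matches.append((r, offset))
    if ism_matches:
        best, offset = min(
            ism_matches,
            key=lambda pair: (_end_distance(t, pair[0]), pair[0].transcript_id),
        )
        rec.category = "ISM"
        rec.associated_genes = [best.gene_id]
        rec.associated_transcript = best.transcript_id
        if offset + len(chain) == len(best.chain):
            rec.ism_subtype = "5prime"  # 3' anchored, 5' exons missing
        elif offset == 0:
            rec.ism_subtype = "3prime"
        else:
            rec.ism_subtype = "internal"
        rec.ir_introns = _retained_introns(t, [ref.genes[best.gene_id]])
        rec.ir_flag = bool(rec.ir_introns)
        return rec

    # (4) fusion: exonic overlap with >=2 mutually non-overlapping genes
    if len(genes) >= 2:
        disjoint = all(
            not _overlap(a.start, a.end, b.start, b.end)
            for i, a in enumerate(genes)
            for b in genes[i + 1 :]
        )
        if disjoint:
            rec.category = "fusion"
            rec.associated_genes = gene_ids
            rec.ir_introns = _retained_introns(t, genes)
            rec.ir_flag = bool(rec.ir_introns)
            return rec

    if genes:
        donors = frozenset().union(*(g.donor_sites for g in genes))
        acceptors = frozenset().union(*(g.acceptor_sites for g in genes))
        t_donors = {d for d, _ in chain}
        t_acceptors = {a for _, a in chain}
        # (5) NIC: every site annotated in the pooled site index
        if t_donors <= donors and t_acceptors <= acceptors:
            rec.category = "NIC"
            rec.associated_genes = gene_ids
            rec.ir_introns = _retained_introns(t, genes)
            rec.ir_flag = bool(rec.ir_introns)
            return rec
        # (6) NNC: >=1 novel site but >=1 shared junction or site
        ref_junctions = {
            j for g in genes for r in g.transcripts for j in r.junctions
        }
        shares = (
            bool(t_donors & donors)
            or bool(t_acceptors & acceptors)
            or bool(set(chain) & ref_junctions)
        )
        if shares:
            rec.category = "NNC"
            rec.associated_genes = gene_ids
            rec.ir_introns = _retained_introns(t, genes)
            rec.ir_flag = bool(rec.ir_introns)
            return rec
        # exonic overlap but no shared splice evidence at all
        rec.category = "genic_genomic"
        rec.associated_genes = gene_ids
        rec.ir_introns = _retained_introns(t, genes)
        rec.ir_flag = bool(rec.ir_introns)
        return rec

    return _classify_nonspliced_overlap(t, ref, genes, gene_ids, rec)


def _classify_nonspliced_overlap(
    t: TranscriptModel,
    ref: GenomeAnnotation,
    genes: Sequence[Gene],
    gene_ids: list[str],
    rec: ClassificationRecord,
) -> ClassificationRecord:
    """Steps (7)-(10): categories that do not rely on shared splice sites."""
    # (7) genic_genomic: same-strand exonic overlap but no shared sites
    if genes:
        rec.category = "genic_genomic"
        rec.associated_genes = gene_ids
        rec.ir_introns = _retained_introns(t, genes)
        rec.ir_flag = bool(rec.ir_introns)
        return rec
    # (8) genic_intron: entirely within one annotated intron, same strand
    for gene in ref.genes_on(t.chrom):
        if gene.strand != t.strand:
            continue
        for s, e in gene.intron_intervals():
            if s <= t.start and t.end <= e:
                rec.category = "genic_intron"
                rec.associated_genes = [gene.gene_id]
                return rec
    # (9) antisense: overlaps a gene only on the opposite strand
    anti = [
        g
        for g in ref.genes_on(t.chrom)
        if g.strand != t.strand and _overlap(t.start, t.end, g.start, g.end)
    ]
    if anti:
        rec.category = "antisense"
        rec.associated_genes = [g.gene_id for g in anti]
        return rec
    # (10) intergenic
    rec.category = "intergenic"
    return rec


# ---------------------------------------------------------------------------
# artifact filters


@dataclass
class FilterReport:
    removed_fragment_ids: list[str]
    removed_intrapriming_ids: list[str]
    surviving: list[TranscriptModel]


def remove_fragments(
    transcripts: Sequence[TranscriptModel],
    tol_3prime: int = DEFAULT_FRAGMENT_3PRIME_TOL,
) -> FilterReport:
    """Remove partial (5'-degradation) transcript models.

    A multi-exonic transcript is removed when its junction chain is a
    contiguous proper *suffix* (in transcription order) of another input
    transcript's chain on the same chromosome and strand and their 3' ends
    lie within ``tol_3prime`` nt.  A mono-exonic transcript is removed when
    it is contained in another transcript's 3'-most exon with its 3' end
    within the same tolerance.  Witnesses are drawn from the full input
    set, which makes the filter idempotent.
    """
    by_loc: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in transcripts:
        by_loc.setdefault((t.chrom, t.strand), []).append(t)

    removed: list[str] = []
    for t in transcripts:
        group = by_loc[(t.chrom, t.strand)]
        chain = t.chain
        is_fragment = False
        for u in group:
            if u.transcript_id == t.transcript_id:
                continue
            if abs(t.tts - u.tts) > tol_3prime:
                continue
            if t.is_monoexonic:
                last_exon = u.exons_transcription_order()[-1]
                if last_exon.contains(t.exons[0]):
                    is_fragment = True
                    break
            else:
                u_chain = u.chain
                if len(chain) < len(u_chain) and u_chain[-len(chain):] == chain:
                    is_fragment = True
                    break
        if is_fragment:
            removed.append(t.transcript_id)

    removed_set = set(removed)
    surviving = [t for t in transcripts if t.transcript_id not in removed_set]
    return FilterReport(removed, [], surviving)


def intrapriming_fraction(
    t: TranscriptModel,
    genome: SequenceStore,
    window: int = DEFAULT_INTRAPRIMING_WINDOW,
    threshold: float = DEFAULT_INTRAPRIMING_RATE,
) -> tuple[float, bool]:
    """Fraction of adenines in the genomic window downstream of the 3' end.

    The window is read on the transcript's strand (genomic T on the minus
    strand counts as A).  The flag fires at fraction >= threshold.  A
    window extending past the chromosome end is truncated.
    """
    if t.strand == "+":
        seq = genome.fetch_clipped(t.chrom, t.end, t.end + window)
        a = seq.count("A")
    else:
        seq = genome.fetch_clipped(t.chrom, t.start - window, t.start)
        a = seq.count("T")
    if not seq:
        return 0.0, False
    frac = a / len(seq)
    return frac, frac >= threshold


def polya_motif_scan(
    t: TranscriptModel,
    genome: SequenceStore,
    motifs: Sequence[str],
    window: int = DEFAULT_POLYA_WINDOW,
) -> tuple[str, int] | None:
    """Scan the last ``window`` nt of the transcript for a polyA motif.

    Returns (motif, distance of motif end from the 3' terminus) for the
    motif ending closest to the 3' end; ties are broken by motif list
    order.  Returns None when no motif matches.
    """
    if not motifs:
        return None
    seq = transcript_sequence(t, genome)
    tail = seq[-window:]
    best: tuple[int, int, str] | None = None  # (dist, motif_rank, motif)
    for rank, motif in enumerate(motifs):
        pos = tail.find(motif)
        while pos != -1:
            dist = len(tail) - (pos + len(motif))
            cand = (dist, rank, motif)
            if best is None or cand < best:
                best = cand
            pos = tail.find(motif, pos + 1)
    if best is None:
        return None
    return best[2], best[0]


def cage_distance(
    t: TranscriptModel,
    peaks: Sequence[GenomicInterval],
    window: int = DEFAULT_CAGE_WINDOW,
) -> tuple[int, bool] | None:
    """Signed distance from the TSS to the nearest CAGE peak edge.

    0 when the TSS lies inside a peak; negative when the nearest peak is
    upstream of the TSS in transcription orientation.  Returns None when
    no peak exists on the transcript's chromosome.
    """
    tss = t.tss
    best: tuple[int, int] | None = None  # (|d|, signed d)
    for p in peaks:
        if p.chrom != t.chrom:
            continue
        if p.start <= tss <= p.end:
            d = 0
        elif tss < p.start:
            gap = p.start - tss
            # peak right of TSS: downstream on +, upstream on -
            d = gap if t.strand == "+" else -gap
        else:
            gap = tss - p.end
            d = -gap if t.strand == "+" else gap
        cand = (abs(d), d)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    return best[1], abs(best[1]) <= window


# ---------------------------------------------------------------------------
# batch driver


def classify_all(
    transcripts: Sequence[TranscriptModel],
    ref: GenomeAnnotation,
    genome: SequenceStore | None = None,
    cage_peaks: Sequence[GenomicInterval] | None = None,
    polya_motifs: Sequence[str] | None = None,
    lncRNA_genes: Iterable[str] | None = None,
    intrapriming_rate: float = DEFAULT_INTRAPRIMING_RATE,
) -> list[ClassificationRecord]:
    """Classify every transcript, filling optional annotation columns only
    when their inputs are supplied."""
    lnc = set(lncRNA_genes or ())
    records = []
    for t in transcripts:
        rec = classify_transcript(t, ref)
        if genome is not None:
            frac, flag = intrapriming_fraction(t, genome, threshold=intrapriming_rate)
            rec.frac_A_downstream = frac
            rec.intrapriming_flag = flag
            if polya_motifs:
                hit = polya_motif_scan(t, genome, polya_motifs)
                if hit is not None:
                    rec.polya_motif, rec.polya_dist = hit
        if cage_peaks is not None:
            hit = cage_distance(t, cage_peaks)
            if hit is not None:
                rec.dist_to_cage, rec.within_cage_50 = hit
        if lnc and rec.associated_genes:
            rec.lncRNA_flag = any(g in lnc for g in rec.associated_genes)
        records.append(rec)
    return records


def remove_intrapriming(
    transcripts: Sequence[TranscriptModel],
    records: Sequence[ClassificationRecord],
    spare_categories: tuple[str, ...] = ("FSM",),
) -> FilterReport:
    """Drop intrapriming-flagged transcripts outside ``spare_categories``.

    FSM transcripts are spared by default: their 3' ends match annotation
    and are independently supported.
    """
    by_id = {r.transcript_id: r for r in records}
    removed = [
        t.transcript_id
        for t in transcripts
        if (r := by_id.get(t.transcript_id)) is not None
        and r.intrapriming_flag
        and r.category not in spare_categories
    ]
    removed_set = set(removed)
    surviving = [t for t in transcripts if t.transcript_id not in removed_set]
    return FilterReport([], removed, surviving)


def classification_table(records: Sequence[ClassificationRecord]) -> pd.DataFrame:
    """Flatten classification records into a DataFrame (one row per
    transcript), the layout written to the classification TSV."""
    rows = []
    for r in records:
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "category": r.category,
                "associated_genes": ";".join(r.associated_genes),
                "associated_transcript": r.associated_transcript,
                "length": r.length,
                "n_exons": r.n_exons,
                "ir_flag": r.ir_flag,
                "ism_subtype": r.ism_subtype,
                "novel_flag": r.novel_flag,
                "dist_to_cage": r.dist_to_cage,
                "within_cage_50": r.within_cage_50,
                "polya_motif": r.polya_motif,
                "polya_dist": r.polya_dist,
                "frac_A_downstream": r.frac_A_downstream,
                "intrapriming_flag": r.intrapriming_flag,
                "lncRNA_flag": r.lncRNA_flag,
            }
        )
    return pd.DataFrame(rows)
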