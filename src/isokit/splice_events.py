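"""Local alternative-splicing event enumeration from junction coordinates.

Events are defined pairwise between the multi-exonic transcripts detected
for a gene, in the local-event taxonomy used by transcript-level AS
catalogs: skipped exon (SE), mutually exclusive exons (MX), alternative
5'/3' splice site (A5/A3) and alternative first/last exon (AF/AL).
Intron retention (IR) is counted against the reference annotation (via
the classification's ir_flag), not pairwise.

All definitions are written once on a strand-free "transcription axis":
minus-strand coordinates are negated so that every transcript reads
left-to-right with numerically increasing donors/acceptors.  Event keys
are reported as genomic coordinates in transcription order and
deduplicated within each gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classify import ClassificationRecord
from .models import TranscriptModel

EVENT_TYPES = ("SE", "MX", "A5", "A3", "AF", "AL", "IR")

#: fixed tie-break order for the per-gene predominant event type
PREDOMINANCE_ORDER = ("AF", "SE", "A3", "A5", "AL", "MX", "IR")


@dataclass
class SpliceEvent:
    event_type: str
    gene_id: str
    key: tuple[int, ...]
    inclusion_transcripts: list[str] = field(default_factory=list)
    exclusion_transcripts: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# transcription-axis view of a transcript


class _TxView:
    """Exons and junctions of one transcript on the transcription axis
    (minus-strand genomic coordinates negated)."""

    __slots__ = ("tid", "sign", "exons", "junctions")

    def __init__(self, t: TranscriptModel):
        self.tid = t.transcript_id
        self.sign = 1 if t.strand == "+" else -1
        if t.strand == "+":
            self.exons = [(e.start, e.end) for e in t.exons]
        else:
            self.exons = [(-e.end, -e.start) for e in reversed(t.exons)]
        self.junctions = [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def back(self, coord: int) -> int:
        return coord * self.sign

    def exon_covering(self, start: int, end: int) -> bool:
        return any(s <= start and end <= e for s, e in self.exons)


def _pair_events(a: _TxView, b: _TxView) -> list[tuple[str, tuple[int, ...], str, str]]:
    """All events between one ordered transcript pair on the transcription
    axis.  Returns (type, axis key, inclusion tid, exclusion tid)."""
    out = []
    ja, jb = a.junctions, b.junctions
    set_b = set(jb)
    set_a = set(ja)

    # SE: a has consecutive (d1,a1),(d2,a2); b has (d1,a2)
    for (d1, a1), (d2, a2) in zip(ja, ja[1:]):
        if (d1, a2) in set_b:
            out.append(("SE", (d1, a1, d2, a2), a.tid, b.tid))
    for (d1, a1), (d2, a2) in zip(jb, jb[1:]):
        if (d1, a2) in set_a:
            out.append(("SE", (d1, a1, d2, a2), b.tid, a.tid))

    # MX: a has consecutive (d0,a1),(d1p,a3); b has consecutive (d0,a2),(d2p,a3)
    # with non-overlapping middle exons
    for (da0, aa1), (da1, aa3) in zip(ja, ja[1:]):
        for (db0, ab2), (db2, ab3) in zip(jb, jb[1:]):
            if da0 != db0 or aa3 != ab3:
                continue
            if (aa1, da1) == (ab2, db2):
                continue
            # middle exons [aa1, da1) and [ab2, db2) must not overlap
            if aa1 < db2 and ab2 < da1:
                continue
            if aa1 < ab2:
                key = (da0, aa1, da1, ab2, db2, aa3)
                inc, exc = a.tid, b.tid
            else:
                key = (da0, ab2, db2, aa1, da1, aa3)
                inc, exc = b.tid, a.tid
            out.append(("MX", key, inc, exc))

    first_a, first_b = a.exons[0], b.exons[0]
    last_a, last_b = a.exons[-1], b.exons[-1]

    # AF: non-overlapping first exons whose first junctions share an acceptor
    af_keys = set()
    if ja and jb and ja[0][1] == jb[0][1] and ja[0] != jb[0]:
        if not (first_a[0] < first_b[1] and first_b[0] < first_a[1]):
            if first_a[0] < first_b[0]:
                key = first_a + first_b + (ja[0][1],)
                inc, exc = a.tid, b.tid
            else:
                key = first_b + first_a + (ja[0][1],)
                inc, exc = b.tid, a.tid
            af_keys.add((ja[0][0], jb[0][0], ja[0][1]))
            af_keys.add((jb[0][0], ja[0][0], ja[0][1]))
            out.append(("AF", key, inc, exc))

    # AL: non-overlapping last exons whose last junctions share a donor
    al_keys = set()
    if ja and jb and ja[-1][0] == jb[-1][0] and ja[-1] != jb[-1]:
        if not (last_a[0] < last_b[1] and last_b[0] < last_a[1]):
            if last_a[0] < last_b[0]:
                key = (ja[-1][0],) + last_a + last_b
                inc, exc = a.tid, b.tid
            else:
                key = (ja[-1][0],) + last_b + last_a
                inc, exc = b.tid, a.tid
            al_keys.add((ja[-1][0], ja[-1][1], jb[-1][1]))
            al_keys.add((ja[-1][0], jb[-1][1], ja[-1][1]))
            out.append(("AL", key, inc, exc))

    # A5: junctions sharing the acceptor, differing in donor; the
    # inter-donor segment must be exonic in the transcript with the
    # downstream (inner) donor.
    for ia, (da, aa) in enumerate(ja):
        for ib, (db, ab) in enumerate(jb):
            if aa != ab or da == db:
                continue
            d_out, d_in = min(da, db), max(da, db)
            inner = a if d_in == da else b
            outer_tid = b.tid if d_in == da else a.tid
            if not inner.exon_covering(d_out, d_in):
                continue
            # suppressed when the same junction pair is already an AF event
            if ia == 0 and ib == 0 and (da, db, aa) in af_keys:
                continue
            out.append(("A5", (d_out, d_in, aa), inner.tid, outer_tid))

    # A3: junctions sharing the donor, differing in acceptor; the
    # inter-acceptor segment must be exonic in the transcript with the
    # upstream (inner) acceptor.
    for ia, (da, aa) in enumerate(ja):
        for ib, (db, ab) in enumerate(jb):
            if da != db or aa == ab:
                continue
            a_in, a_out = min(aa, ab), max(aa, ab)
            inner = a if a_in == aa else b
            outer_tid = b.tid if a_in == aa else a.tid
            if not inner.exon_covering(a_in, a_out):
                continue
            if ia == len(ja) - 1 and ib == len(jb) - 1 and (da, aa, ab) in al_keys:
                continue
            out.append(("A3", (da, a_in, a_out), inner.tid, outer_tid))

    return out


def enumerate_events(
    transcripts: Sequence[TranscriptModel], gene_id: str
) -> list[SpliceEvent]:
    """Deduplicated local AS events among one gene's transcripts.

    Only multi-exonic transcripts participate.  Events found in several
    transcript pairs are merged by (type, key), accumulating the
    supporting inclusion/exclusion transcript lists.
    """
    views = [_TxView(t) for t in transcripts if not t.is_monoexonic]
    merged: dict[tuple[str, tuple[int, ...]], SpliceEvent] = {}
    for a, b in combinations(views, 2):
        for etype, axis_key, inc, exc in _pair_events(a, b):
            key = tuple(a.back(c) for c in axis_key)
            ev = merged.get((etype, key))
            if ev is None:
                ev = SpliceEvent(etype, gene_id, key)
                merged[(etype, key)] = ev
            if inc not in ev.inclusion_transcripts:
                ev.inclusion_transcripts.append(inc)
            if exc not in ev.exclusion_transcripts:
                ev.exclusion_transcripts.append(exc)
    return sorted(merged.values(), key=lambda e: (e.event_type, e.key))


# ---------------------------------------------------------------------------
# catalog


def group_transcripts_by_gene(
    transcripts: Sequence[TranscriptModel],
    records: Sequence[ClassificationRecord],
) -> dict[str, list[TranscriptModel]]:
    """Gene grouping for event enumeration.

    Transcripts take the (first) associated gene from classification;
    transcripts without one (novel intergenic/antisense genes) are grouped
    into overlap clusters per chromosome and strand under synthetic
    ``novelGene_N`` ids.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    groups: dict[str, list[TranscriptModel]] = {}
    orphans: list[TranscriptModel] = []
    for rec in records:
        t = by_id.get(rec.transcript_id)
        if t is None:
            continue
        if rec.associated_genes and rec.category not in ("antisense", "intergenic"):
            groups.setdefault(rec.associated_genes[0], []).append(t)
        else:
            orphans.append(t)
    # overlap clustering of unassigned transcripts
    orphans.sort(key=lambda t: (t.chrom, t.strand, t.start))
    cluster: list[TranscriptModel] = []
    n = 0

    def flush():
        nonlocal n, cluster
        if cluster:
            n += 1
            groups[f"novelGene_{n}"] = cluster
            cluster = []

    prev_end = None
    prev_key = None
    for t in orphans:
        key = (t.chrom, t.strand)
        if cluster and (key != prev_key or t.start >= prev_end):
            flush()
        cluster.append(t)
        prev_end = t.end if prev_end is None or key != prev_key else max(prev_end, t.end)
        prev_key = key
    flush()
    return groups


@dataclass
class EventCatalog:
    events: list[SpliceEvent]

    def per_gene_counts(self) -> pd.DataFrame:
        rows: dict[str, dict[str, int]] = {}
        for ev in self.events:
            rows.setdefault(ev.gene_id, {et: 0 for et in EVENT_TYPES})
            rows[ev.gene_id][ev.event_type] += 1
        df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
        df.index.name = "gene_id"
        return df.sort_index()

    def counts_by_type(self) -> pd.Series:
        s = pd.Series(0, index=list(EVENT_TYPES), dtype=int)
        for ev in self.events:
            s[ev.event_type] += 1
        return s

    def genes_by_type(self) -> pd.Series:
        genes: dict[str, set] = {et: set() for et in EVENT_TYPES}
        for ev in self.events:
            genes[ev.event_type].add(ev.gene_id)
        return pd.Series({et: len(g) for et, g in genes.items()})


def build_catalog(
    transcripts: Sequence[TranscriptModel],
    records: Sequence[ClassificationRecord],
) -> EventCatalog:
    """Enumerate events for every gene group and append IR events taken
    from the classification (one event per retained annotated intron)."""
    groups = group_transcripts_by_gene(transcripts, records)
    events: list[SpliceEvent] = []
    for gene_id in sorted(groups):
        events.extend(enumerate_events(groups[gene_id], gene_id))
    # IR against the reference annotation, keyed by retained intron
    ir_events: dict[tuple[str, tuple[int, int]], SpliceEvent] = {}
    for rec in records:
        if not rec.ir_flag or not rec.associated_genes:
            continue
        gene_id = rec.associated_genes[0]
        for intron in rec.ir_introns:
            ev = ir_events.get((gene_id, intron))
            if ev is None:
                ev = SpliceEvent("IR", gene_id, intron)
                ir_events[(gene_id, intron)] = ev
            if rec.transcript_id not in ev.inclusion_transcripts:
                ev.inclusion_transcripts.append(rec.transcript_id)
    events.extend(ir_events[k] for k in sorted(ir_events))
    return EventCatalog(events)


def ir_aggregate(records: Sequence[ClassificationRecord]) -> dict[str, object]:
    """IR bookkeeping: IR transcripts, IR genes, and genes all of whose
    detected transcripts are IR-flagged."""
    ir_transcripts = [r.transcript_id for r in records if r.ir_flag]
    gene_any: dict[str, bool] = {}
    gene_all: dict[str, bool] = {}
    for r in records:
        for g in r.associated_genes[:1]:
            gene_any[g] = gene_any.get(g, False) or r.ir_flag
            gene_all[g] = gene_all.get(g, True) and r.ir_flag
    ir_genes = sorted(g for g, v in gene_any.items() if v)
    only_ir = sorted(g for g in ir_genes if gene_all[g])
    return {
        "ir_transcripts": ir_transcripts,
        "ir_genes": ir_genes,
        "only_ir_genes": only_ir,
    }


def per_gene_summary(catalog: EventCatalog) -> pd.DataFrame:
    """Per-gene event counts by type plus the predominant type.

    The predominant type is the argmax of per-type event counts; ties are
    broken by the fixed order AF > SE > A3 > A5 > AL > MX > IR.  Genes
    with zero events do not appear.
    """
    counts = catalog.per_gene_counts()
    if counts.empty:
        counts["predominant"] = pd.Series(dtype=object)
        return counts

    def predominant(row: pd.Series) -> str:
        best = row.max()
        for et in PREDOMINANCE_ORDER:
            if row.get(et, 0) == best:
                return et
        return row.idxmax()

    counts["predominant"] = counts[list(EVENT_TYPES)].apply(predominant, axis=1)
    return counts


def write_events(catalog: EventCatalog, path: str | Path) -> None:
    """Write the event catalog as a TSV (one row per deduplicated event,
    stable sort by gene then type then key; byte-deterministic)."""
    rows = sorted(
        catalog.events, key=lambda e: (e.gene_id, e.event_type, e.key)
    )
    with open(path, "w") as fh:
        fh.write("gene_id\tevent_type\tkey\tinclusion\texclusion\n")
        for ev in rows:
            fh.write(
                f"{ev.gene_id}\t{ev.event_type}\t"
                f"{','.join(map(str, ev.key))}\t"
                f"{';'.join(ev.inclusion_transcripts)}\t"
                f"{';'.join(ev.exclusion_transcripts)}\n"
            )


def read_events(path: str | Path) -> EventCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    events = []
    for _, row in df.iterrows():
        events.append(
            SpliceEvent(
                row["event_type"],
                row["gene_id"],
                tuple(int(x) for x in row["key"].split(",")),
                [s for s in row["inclusion"].split(";") if s],
                [s for s in row["exclusion"].split(";") if s],
            )
        )
    return EventCatalog(events)
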