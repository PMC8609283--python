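"""Independent reference implementations used as test oracles.

Each oracle re-derives its quantity directly from the definitions —
exhaustive search, enumeration or closed form — without sharing code
paths with the package implementation it checks.
"""

from __future__ import annotations

import itertools

from isokit.models import GenomeAnnotation, TranscriptModel


# ---------------------------------------------------------------------------
# brute-force structural classification


def _exons_overlap(t: TranscriptModel, u: TranscriptModel) -> bool:
    return any(
        e.start < f.end and f.start < e.end
        for e in t.exons
        for f in u.exons
    )


def _gene_exon_overlap(t, gene) -> bool:
    return any(
        t.chrom == r.chrom and t.strand == r.strand and _exons_overlap(t, r)
        for r in gene.transcripts
    )


def _end_dist(t, r):
    return abs(t.tss - r.tss) + abs(t.tts - r.tts)


def oracle_classify(t: TranscriptModel, ref: GenomeAnnotation):
    """Exhaustive-search classification: every reference transcript and
    gene is compared directly against the definitions.  Returns
    (category, associated gene set, associated transcript)."""
    genes = [
        g
        for g in ref.genes.values()
        if g.chrom == t.chrom and g.strand == t.strand and _gene_exon_overlap(t, g)
    ]
    gene_ids = {g.gene_id for g in genes}

    if t.is_monoexonic:
        matches = [
            r
            for g in genes
            for r in g.transcripts
            if r.is_monoexonic and r.start <= t.start and t.end <= r.end
        ]
        if matches:
            best = min(matches, key=lambda r: (_end_dist(t, r), r.transcript_id))
            return "FSM", {best.gene_id}, best.transcript_id
    else:
        chain = list(t.junctions)
        # FSM: search every multi-exonic reference transcript
        fsm = [
            r
            for g in ref.genes.values()
            if g.chrom == t.chrom and g.strand == t.strand
            for r in g.transcripts
            if not r.is_monoexonic and list(r.junctions) == chain
        ]
        if fsm:
            best = min(fsm, key=lambda r: (_end_dist(t, r), r.transcript_id))
            return "FSM", {best.gene_id}, best.transcript_id
        # ISM: every window of every reference chain
        ism = []
        for g in genes:
            for r in g.transcripts:
                rc = list(r.junctions)
                for i in range(len(rc)):
                    if rc[i : i + len(chain)] == chain and len(chain) < len(rc):
                        ism.append(r)
                        break
        if ism:
            best = min(ism, key=lambda r: (_end_dist(t, r), r.transcript_id))
            return "ISM", {best.gene_id}, best.transcript_id
        # fusion
        if len(genes) >= 2 and all(
            a.end <= b.start or b.end <= a.start
            for a, b in itertools.combinations(genes, 2)
        ):
            return "fusion", gene_ids, "novel"
        if genes:
            donors = {d for g in genes for r in g.transcripts for d, _ in r.junctions}
            acceptors = {a for g in genes for r in g.transcripts for _, a in r.junctions}
            junctions = {j for g in genes for r in g.transcripts for j in r.junctions}
            t_d = {d for d, _ in chain}
            t_a = {a for _, a in chain}
            if t_d <= donors and t_a <= acceptors:
                return "NIC", gene_ids, "novel"
            if (t_d & donors) or (t_a & acceptors) or (set(chain) & junctions):
                return "NNC", gene_ids, "novel"
            return "genic_genomic", gene_ids, "novel"

    if genes:
        return "genic_genomic", gene_ids, "novel"
    for g in ref.genes.values():
        if g.chrom != t.chrom or g.strand != t.strand:
            continue
        for r in g.transcripts:
            for s, e in r.introns:
                if s <= t.start and t.end <= e:
                    return "genic_intron", {g.gene_id}, "novel"
    anti = {
        g.gene_id
        for g in ref.genes.values()
        if g.chrom == t.chrom
        and g.strand != t.strand
        and t.start < g.end
        and g.start < t.end
    }
    if anti:
        return "antisense", anti, "novel"
    return "intergenic", set(), "novel"


# ---------------------------------------------------------------------------
# pairwise AS-event oracle


def _tx_geometry(t: TranscriptModel):
    """Transcription-order exon and junction lists with an explicit
    'comes before in transcription' comparator."""
    exons = t.exons_transcription_order()
    juncs = list(t.junctions)
    if t.strand == "+":
        before = lambda x, y: x < y
    else:
        before = lambda x, y: x > y
    return exons, juncs, before


def oracle_events(transcripts) -> set[tuple[str, tuple[int, ...]]]:
    """Direct pairwise application of the event definitions, then key
    dedup.  Returns the set of (event type, genomic key)."""
    found: set[tuple[str, tuple[int, ...]]] = set()
    multi = [t for t in transcripts if not t.is_monoexonic]
    for t1, t2 in itertools.combinations(multi, 2):
        e1, j1, before = _tx_geometry(t1)
        e2, j2, _ = _tx_geometry(t2)

        def exonic(t_exons, a, b):
            """Is the transcription-order segment a..b exonic?"""
            lo, hi = (a, b) if a < b else (b, a)
            return any(e.start <= lo and hi <= e.end for e in t_exons)

        # SE (both directions)
        for (inc_j, exc_j) in ((j1, j2), (j2, j1)):
            for i in range(len(inc_j) - 1):
                (d1, a1), (d2, a2) = inc_j[i], inc_j[i + 1]
                if (d1, a2) in exc_j:
                    found.add(("SE", (d1, a1, d2, a2)))
        # MX
        for i in range(len(j1) - 1):
            for k in range(len(j2) - 1):
                (d0, a1), (dp, a3) = j1[i], j1[i + 1]
                (e0, b2), (ep, b3) = j2[k], j2[k + 1]
                if d0 != e0 or a3 != b3 or (a1, dp) == (b2, ep):
                    continue
                m1 = sorted((a1, dp))
                m2 = sorted((b2, ep))
                if m1[0] < m2[1] and m2[0] < m1[1]:
                    continue
                if before(a1, b2):
                    found.add(("MX", (d0, a1, dp, b2, ep, a3)))
                else:
                    found.add(("MX", (d0, b2, ep, a1, dp, a3)))
        # AF / AL
        af_pairs = set()
        al_pairs = set()
        f1, f2 = e1[0], e2[0]
        if j1 and j2 and j1[0][1] == j2[0][1] and j1[0] != j2[0]:
            if f1.end <= f2.start or f2.end <= f1.start:
                af_pairs.add(frozenset([j1[0], j2[0]]))
                if before(f1.start if t1.strand == "+" else f1.end,
                          f2.start if t1.strand == "+" else f2.end):
                    first, second = f1, f2
                else:
                    first, second = f2, f1
                if t1.strand == "+":
                    key = (first.start, first.end, second.start, second.end, j1[0][1])
                else:
                    key = (first.end, first.start, second.end, second.start, j1[0][1])
                found.add(("AF", key))
        l1, l2 = e1[-1], e2[-1]
        if j1 and j2 and j1[-1][0] == j2[-1][0] and j1[-1] != j2[-1]:
            if l1.end <= l2.start or l2.end <= l1.start:
                al_pairs.add(frozenset([j1[-1], j2[-1]]))
                if before(l1.start if t1.strand == "+" else l1.end,
                          l2.start if t1.strand == "+" else l2.end):
                    first, second = l1, l2
                else:
                    first, second = l2, l1
                if t1.strand == "+":
                    key = (j1[-1][0], first.start, first.end, second.start, second.end)
                else:
                    key = (j1[-1][0], first.end, first.start, second.end, second.start)
                found.add(("AL", key))
        # A5 / A3
        for i, (da, aa) in enumerate(j1):
            for k, (db, ab) in enumerate(j2):
                if aa == ab and da != db:
                    if before(da, db):
                        outer, inner, inner_t = da, db, (e2, t2)
                    else:
                        outer, inner, inner_t = db, da, (e1, t1)
                    if exonic(inner_t[0], outer, inner):
                        if (
                            i == 0
                            and k == 0
                            and frozenset([j1[0], j2[0]]) in af_pairs
                        ):
                            continue
                        found.add(("A5", (outer, inner, aa)))
                if da == db and aa != ab:
                    if before(aa, ab):
                        inner, outer, inner_t = aa, ab, (e1, t1)
                    else:
                        inner, outer, inner_t = ab, aa, (e2, t2)
                    if exonic(inner_t[0], inner, outer):
                        if (
                            i == len(j1) - 1
                            and k == len(j2) - 1
                            and frozenset([j1[-1], j2[-1]]) in al_pairs
                        ):
                            continue
                        found.add(("A3", (da, inner, outer)))
    return found


# ---------------------------------------------------------------------------
# ORF enumeration


def oracle_longest_orf(seq: str) -> tuple[int, int] | None:
    """All (ATG, stop) pairs enumerated; longest clean span wins, ties to
    the 5'-most start.  Returns (start, end) with the stop included."""
    seq = seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    candidates = []
    for s in range(len(seq) - 2):
        if seq[s : s + 3] != "ATG":
            continue
        for e in range(s + 3, len(seq) - 2, 3):
            codon = seq[e : e + 3]
            if codon in stops:
                candidates.append((s, e + 3))
                break
    if not candidates:
        return None
    return min(candidates, key=lambda c: (-(c[1] - c[0]), c[0]))


# ---------------------------------------------------------------------------
# exact rank-sum enumeration


def oracle_ranksum_p(a, b) -> float:
    """Two-sided exact rank-sum p by complete enumeration of labelings."""
    pooled = list(a) + list(b)
    n = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def w(idx):
        return sum(ranks[pooled[i]] for i in idx)

    obs = w(range(n))
    ws = [w(c) for c in itertools.combinations(range(len(pooled)), n)]
    total = len(ws)
    lo = sum(1 for x in ws if x <= obs)
    hi = sum(1 for x in ws if x >= obs)
    return min(1.0, 2.0 * min(lo, hi) / total)
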