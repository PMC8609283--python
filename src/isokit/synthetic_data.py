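"""Seeded synthetic data with complete ground truth.

The generator emulates the statistical structure of a long-read cortex
transcriptome experiment at desk scale: a multi-gene reference annotation
whose genes share per-gene splice-site pools, query transcript models
planted for every structural category (FSM, ISM, NIC, NNC, fusion,
antisense, intergenic, genic_genomic, genic_intron), retained-intron and
NMD constructs, 5'-degradation fragments, intrapriming A-tracts, CAGE
peaks jittered around reference TSSs, and negative-binomial full-length
counts with planted isoform switches between two sample groups.

Constructions are arranged so that every planted label is unambiguous
under exact junction-chain matching: 3' ends of sub-chain constructs are
offset beyond the fragment filter's tolerance, planted fragments keep the
parent 3' end, designed ORFs are the only ATG-initiated reading frames of
their transcripts, and the 20-nt windows downstream of non-intraprimed
3' ends are rewritten to a fixed 25% A pattern.  A rejection check (with
a hard cap) guards the few spots where a random draw could create an
ambiguous construct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import write_gtf
from .models import (
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    SequenceStore,
    TranscriptModel,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
SCRUB_PATTERN = "ACGT" * 5  # 25% A on either strand
REJECTION_CAP = 200


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions
    every planted-truth test runs under."""

    seed: int = 0
    n_chroms: int = 3
    gene_spacing: int = 1500
    locus_margin: int = 400
    exon_count_range: tuple[int, int] = (4, 8)
    exon_length_range: tuple[int, int] = (100, 250)
    terminal_exon_min: int = 180
    intron_length_range: tuple[int, int] = (150, 400)
    transcripts_per_gene_range: tuple[int, int] = (2, 4)
    category_quota: dict = field(
        default_factory=lambda: {
            "FSM": 220,
            "ISM": 60,
            "NIC": 120,
            "NNC": 45,
            "fusion": 6,
            "antisense": 6,
            "intergenic": 6,
            "genic_genomic": 6,
            "genic_intron": 6,
        }
    )
    ir_quota: int = 20
    nmd_quota: tuple[int, int] = (10, 10)  # (stop before junction, after)
    fragment_quota: int = 15
    intrapriming_fraction: float = 0.1
    ism_3prime_offset: int = 150
    intrapriming_extension: int = 200
    cage_jitter_sd: float = 10.0
    cage_peak_width: int = 20
    nb_mean_range: tuple[float, float] = (10.0, 200.0)
    nb_dispersion: float = 0.3
    samples_per_group: tuple[int, int] = (4, 3)
    cells_per_sample: int = 2
    group_names: tuple[str, str] = ("adult", "fetal")
    dtu_gene_quota: int = 5
    dtu_means: tuple[float, float] = (60.0, 5.0)
    queries_per_gene: int = 3


@dataclass
class TruthSet:
    """Ground-truth labels for every generated entity."""

    category: dict[str, str] = field(default_factory=dict)
    gene: dict[str, str] = field(default_factory=dict)
    ir: dict[str, bool] = field(default_factory=dict)
    nmd: dict[str, bool] = field(default_factory=dict)  # designed only
    fragment: dict[str, bool] = field(default_factory=dict)
    intrapriming: dict[str, bool] = field(default_factory=dict)
    dtu_genes: dict[str, tuple[str, str]] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: SequenceStore
    annotation: GenomeAnnotation
    reference_transcripts: list[TranscriptModel]
    queries: list[TranscriptModel]
    truth: TruthSet
    cage_peaks: list[GenomicInterval]
    counts: pd.DataFrame | None = None
    groups: pd.Series | None = None


# ---------------------------------------------------------------------------
# geometry helpers (strand-aware 3'/5' edits on genomic exon lists)


def _trim_3prime(exons: list[GenomicInterval], strand: str, d: int) -> list[GenomicInterval]:
    exons = list(exons)
    if strand == "+":
        e = exons[-1]
        exons[-1] = GenomicInterval(e.chrom, e.start, e.end - d, e.strand)
    else:
        e = exons[0]
        exons[0] = GenomicInterval(e.chrom, e.start + d, e.end, e.strand)
    return exons


def _extend_3prime(exons: list[GenomicInterval], strand: str, d: int) -> list[GenomicInterval]:
    return _trim_3prime(exons, strand, -d)


def _trim_5prime(exons: list[GenomicInterval], strand: str, d: int) -> list[GenomicInterval]:
    exons = list(exons)
    if strand == "+":
        e = exons[0]
        exons[0] = GenomicInterval(e.chrom, e.start + d, e.end, e.strand)
    else:
        e = exons[-1]
        exons[-1] = GenomicInterval(e.chrom, e.start, e.end - d, e.strand)
    return exons


def _downstream_window(t: TranscriptModel, w: int) -> tuple[int, int]:
    if t.strand == "+":
        return (t.end, t.end + w)
    return (t.start - w, t.start)


# ---------------------------------------------------------------------------
# builder


@dataclass
class _GeneBuild:
    gene: Gene
    master_exons: list[GenomicInterval]
    full_transcript: TranscriptModel
    used_internal_skips: set[int] = field(default_factory=set)
    long_intron: int | None = None  # genomic intron index
    ism_planted: bool = False
    gg_planted: bool = False


class _Simulator:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.cursors = {f"chr{i + 1}": 1000 for i in range(config.n_chroms)}
        self._chrom_cycle = 0
        self.gene_builds: list[_GeneBuild] = []
        self.pair_loci: list[tuple[_GeneBuild, _GeneBuild]] = []
        self.nested_hosts: list[_GeneBuild] = []
        self.nmd_genes: list[_GeneBuild] = []
        self.deserts: list[tuple[str, int, int]] = []
        self.queries: list[TranscriptModel] = []
        self.truth = TruthSet()
        self._tid = 0
        self._gid = 0
        self._genome_writes: list[tuple[str, int, str]] = []
        self._windows: dict[tuple[str, int], tuple[int, str]] = {}

    # -- id & placement helpers -------------------------------------------

    def _next_gene_id(self) -> str:
        self._gid += 1
        return f"SIMG{self._gid:05d}"

    def _next_tid(self, prefix: str) -> str:
        self._tid += 1
        return f"{prefix}.{self._tid:05d}"

    def _place(self, width: int) -> tuple[str, int]:
        """Reserve a region of the given width on the next chromosome."""
        chrom = f"chr{(self._chrom_cycle % self.cfg.n_chroms) + 1}"
        self._chrom_cycle += 1
        start = self.cursors[chrom] + self.cfg.locus_margin
        self.cursors[chrom] = start + width + self.cfg.locus_margin + self.cfg.gene_spacing
        return chrom, start

    # -- reference construction -------------------------------------------

    def _build_gene(
        self, chrom: str, start: int, strand: str, long_intron: bool = False
    ) -> _GeneBuild:
        cfg, rng = self.cfg, self.rng
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        exons = []
        pos = start
        for i in range(n_exons):
            lo, hi = cfg.exon_length_range
            length = int(rng.integers(lo, hi + 1))
            if i in (0, n_exons - 1):
                length = max(length, cfg.terminal_exon_min)
            exons.append(GenomicInterval(chrom, pos, pos + length, strand))
            if i < n_exons - 1:
                if long_intron and i == 0:
                    intron = 600
                else:
                    intron = int(
                        rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1)
                    )
                pos = pos + length + intron
        gid = self._next_gene_id()
        full = TranscriptModel(f"{gid}.t1", gid, chrom, strand, exons)
        transcripts = [full]
        build = _GeneBuild(
            gene=Gene(gid, chrom, strand, exons[0].start, exons[-1].end, transcripts),
            master_exons=exons,
            full_transcript=full,
            long_intron=0 if long_intron else None,
        )
        # variants sharing the site pool
        n_variants = int(
            rng.integers(cfg.transcripts_per_gene_range[0], cfg.transcripts_per_gene_range[1] + 1)
        ) - 1
        internal = list(range(1, n_exons - 1))
        v = 1
        for _ in range(n_variants):
            kind = rng.choice(["skip", "alt_first"])
            if kind == "skip":
                free = [j for j in internal if j not in build.used_internal_skips]
                if not free:
                    continue
                j = int(rng.choice(free))
                build.used_internal_skips.add(j)
                var_exons = exons[:j] + exons[j + 1 :]
            else:
                # alternative first exon, upstream in transcription
                length = int(rng.integers(100, 161))
                gap = int(rng.integers(100, 201))
                if strand == "+":
                    new = GenomicInterval(
                        chrom, exons[0].start - gap - length, exons[0].start - gap, strand
                    )
                    var_exons = [new] + exons[1:]
                else:
                    new = GenomicInterval(
                        chrom, exons[-1].end + gap, exons[-1].end + gap + length, strand
                    )
                    var_exons = exons[:-1] + [new]
            v += 1
            var = TranscriptModel(f"{gid}.t{v}", gid, chrom, strand, var_exons)
            if any(var.chain == t.chain for t in transcripts):
                continue
            transcripts.append(var)
        g = build.gene
        g.start = min(t.start for t in transcripts)
        g.end = max(t.end for t in transcripts)
        return build

    def build_reference(self) -> None:
        cfg = self.cfg
        q = cfg.category_quota
        plain_queries = (
            q["FSM"] + q["ISM"] + q["NIC"] + q["NNC"]
            + q["genic_genomic"] + q["genic_intron"]
            + cfg.ir_quota + cfg.fragment_quota
        )
        if cfg.fragment_quota > q["FSM"]:
            raise ValueError("fragment_quota must not exceed the FSM quota")
        n_plain = max(math.ceil(plain_queries / cfg.queries_per_gene), 8)
        n_long_intron = q["genic_intron"]
        gene_width = 5600
        for i in range(n_plain):
            strand = "+" if self.rng.random() < 0.5 else "-"
            chrom, start = self._place(gene_width)
            self.gene_builds.append(
                self._build_gene(chrom, start, strand, long_intron=i < n_long_intron)
            )
        for _ in range(q["fusion"]):
            strand = "+" if self.rng.random() < 0.5 else "-"
            chrom, start = self._place(2 * gene_width + 300)
            a = self._build_gene(chrom, start, strand)
            b = self._build_gene(chrom, a.gene.end + 300 + self.cfg.locus_margin, strand)
            self.pair_loci.append((a, b))
        for _ in range(q["antisense"]):
            strand = "+" if self.rng.random() < 0.5 else "-"
            chrom, start = self._place(gene_width)
            self.nested_hosts.append(self._build_gene(chrom, start, strand))
        for _ in range(sum(cfg.nmd_quota)):
            strand = "+" if self.rng.random() < 0.5 else "-"
            chrom, start = self._place(gene_width)
            self.nmd_genes.append(self._build_gene(chrom, start, strand))
        for _ in range(q["intergenic"]):
            chrom, start = self._place(2000)
            self.deserts.append((chrom, start, start + 2000))

    @property
    def all_builds(self) -> list[_GeneBuild]:
        return (
            self.gene_builds
            + [g for pair in self.pair_loci for g in pair]
            + self.nested_hosts
            + self.nmd_genes
        )

    def annotation(self) -> GenomeAnnotation:
        return GenomeAnnotation([b.gene for b in self.all_builds])

    # -- query constructions ----------------------------------------------

    def _emit(
        self,
        prefix: str,
        exons: list[GenomicInterval],
        gene_id: str | None,
        category: str,
        ir: bool = False,
        fragment: bool = False,
    ) -> TranscriptModel:
        tid = self._next_tid(prefix)
        t = TranscriptModel(tid, gene_id, exons[0].chrom, exons[0].strand, exons)
        self.queries.append(t)
        self.truth.category[tid] = category
        if gene_id is not None:
            self.truth.gene[tid] = gene_id
        self.truth.ir[tid] = ir
        self.truth.fragment[tid] = fragment
        self.truth.intrapriming[tid] = False
        return t

    def make_fsm(self, b: _GeneBuild) -> TranscriptModel:
        refs = [t for t in b.gene.transcripts if not t.is_monoexonic]
        ref = refs[int(self.rng.integers(len(refs)))]
        first_len = len(ref.exons_transcription_order()[0])
        jitter = int(self.rng.integers(0, min(31, max(1, first_len - 50))))
        exons = _trim_5prime(ref.exons, ref.strand, jitter)
        return self._emit("FSM", exons, b.gene.gene_id, "FSM")

    def make_ism(self, b: _GeneBuild) -> TranscriptModel:
        ref = b.full_transcript
        n_j = len(ref.chain)
        k = int(self.rng.integers(1, n_j))  # junctions dropped at the 5' end
        exons_tx = ref.exons_transcription_order()[k:]
        exons = sorted(exons_tx, key=lambda e: e.start)
        exons = _trim_3prime(exons, ref.strand, self.cfg.ism_3prime_offset)
        b.ism_planted = True
        return self._emit("ISM", exons, b.gene.gene_id, "ISM")

    def make_nic(self, b: _GeneBuild) -> TranscriptModel | None:
        n = len(b.master_exons)
        free = [
            j for j in range(1, n - 1) if j not in b.used_internal_skips
        ]
        if not free:
            return None
        j = int(self.rng.choice(free))
        b.used_internal_skips.add(j)
        exons = b.master_exons[:j] + b.master_exons[j + 1 :]
        return self._emit("NIC", exons, b.gene.gene_id, "NIC")

    def make_nnc(self, b: _GeneBuild) -> TranscriptModel | None:
        exons = list(b.master_exons)
        n = len(exons)
        donors = b.gene.donor_sites | b.gene.acceptor_sites
        for _ in range(REJECTION_CAP):
            i = int(self.rng.integers(0, n - 1))  # genomic intron index
            delta = int(self.rng.integers(3, 31))
            if exons[0].strand == "+":
                e = exons[i]
                new_end = e.end - delta
                if new_end - e.start < 50 or new_end in donors:
                    continue
                shifted = GenomicInterval(e.chrom, e.start, new_end, e.strand)
                return self._emit(
                    "NNC", exons[:i] + [shifted] + exons[i + 1 :], b.gene.gene_id, "NNC"
                )
            e = exons[i + 1]
            new_start = e.start + delta
            if e.end - new_start < 50 or new_start in donors:
                continue
            shifted = GenomicInterval(e.chrom, new_start, e.end, e.strand)
            return self._emit(
                "NNC", exons[: i + 1] + [shifted] + exons[i + 2 :], b.gene.gene_id, "NNC"
            )
        raise RuntimeError("rejection cap reached planting a novel splice site")

    def make_ir(self, b: _GeneBuild) -> TranscriptModel | None:
        n = len(b.master_exons)
        if n < 4:
            return None
        i = int(self.rng.integers(1, n - 2))  # interior genomic intron
        merged = GenomicInterval(
            b.master_exons[i].chrom,
            b.master_exons[i].start,
            b.master_exons[i + 1].end,
            b.master_exons[i].strand,
        )
        exons = b.master_exons[:i] + [merged] + b.master_exons[i + 2 :]
        return self._emit("IRNIC", exons, b.gene.gene_id, "NIC", ir=True)

    def make_fragment(self, parent: TranscriptModel, b: _GeneBuild) -> TranscriptModel | None:
        n = parent.n_exons
        if n < 3:
            return None
        m = int(self.rng.integers(2, n))  # number of retained 3' exons
        tail = parent.exons_transcription_order()[n - m :]
        exons = sorted(tail, key=lambda e: e.start)
        if len(exons[0 if parent.strand == "+" else -1]) > 60:
            exons = _trim_5prime(exons, parent.strand, 20)
        return self._emit("FRAG", exons, b.gene.gene_id, "ISM", fragment=True)

    def make_genic_genomic(self, b: _GeneBuild) -> TranscriptModel | None:
        if b.gg_planted:
            return None
        b.gg_planted = True
        e = b.master_exons[1]
        if e.strand == "+":
            iv = GenomicInterval(e.chrom, e.end - 60, e.end + 80, e.strand)
        else:
            iv = GenomicInterval(e.chrom, e.start - 80, e.start + 60, e.strand)
        return self._emit("GG", [iv], b.gene.gene_id, "genic_genomic")

    def make_genic_intron(self, b: _GeneBuild) -> TranscriptModel | None:
        if b.long_intron is None:
            return None
        left = b.master_exons[b.long_intron].end
        right = b.master_exons[b.long_intron + 1].start
        iv = GenomicInterval(
            b.master_exons[0].chrom, left + 100, left + 300, b.master_exons[0].strand
        )
        assert iv.end + 120 < right
        return self._emit("GI", [iv], b.gene.gene_id, "genic_intron")

    def make_fusion(self, pair: tuple[_GeneBuild, _GeneBuild]) -> TranscriptModel:
        a, bb = pair
        exons = list(a.full_transcript.exons) + list(bb.full_transcript.exons)
        return self._emit("FUS", exons, None, "fusion")

    def make_antisense(self, host: _GeneBuild) -> TranscriptModel:
        g = host.gene
        anti = "-" if g.strand == "+" else "+"
        s = g.start + 200
        exons = [
            GenomicInterval(g.chrom, s, s + 150, anti),
            GenomicInterval(g.chrom, s + 350, s + 500, anti),
        ]
        return self._emit("AS", exons, None, "antisense")

    def make_intergenic(self, desert: tuple[str, int, int]) -> TranscriptModel:
        chrom, s, _e = desert
        strand = "+" if self.rng.random() < 0.5 else "-"
        exons = [
            GenomicInterval(chrom, s + 100, s + 300, strand),
            GenomicInterval(chrom, s + 500, s + 750, strand),
        ]
        return self._emit("IG", exons, None, "intergenic")

    # -- query scheduling ---------------------------------------------------

    def build_queries(self) -> None:
        cfg = self.cfg
        quota = dict(cfg.category_quota)
        pools = {
            "FSM": quota["FSM"],
            "ISM": quota["ISM"],
            "NIC": quota["NIC"],
            "NNC": quota["NNC"],
            "IR": cfg.ir_quota,
            "FRAG": cfg.fragment_quota,
            "GG": quota["genic_genomic"],
            "GI": quota["genic_intron"],
        }
        order = ["FSM", "NIC", "ISM", "NNC", "IR", "FRAG", "GG", "GI"]
        gi_hosts = [b for b in self.gene_builds if b.long_intron is not None]
        gi_i = 0
        idx = 0
        guard = 0
        while any(pools[k] > 0 for k in order):
            guard += 1
            if guard > 100 * len(self.gene_builds):
                raise RuntimeError("quota scheduling did not converge")
            b = self.gene_builds[idx % len(self.gene_builds)]
            idx += 1
            taken = 0
            fsm_here: TranscriptModel | None = None
            for kind in order:
                if taken >= cfg.queries_per_gene and kind not in ("GG", "GI"):
                    continue
                if pools[kind] <= 0:
                    continue
                if kind == "FSM":
                    fsm_here = self.make_fsm(b)
                    t = fsm_here
                elif kind == "ISM":
                    if b.ism_planted:
                        continue
                    t = self.make_ism(b)
                elif kind == "NIC":
                    t = self.make_nic(b)
                elif kind == "NNC":
                    t = self.make_nnc(b)
                elif kind == "IR":
                    t = self.make_ir(b)
                elif kind == "FRAG":
                    if fsm_here is None or fsm_here.n_exons < 3:
                        continue
                    t = self.make_fragment(fsm_here, b)
                elif kind == "GG":
                    t = self.make_genic_genomic(b)
                elif kind == "GI":
                    if gi_i >= len(gi_hosts):
                        continue
                    t = self.make_genic_intron(gi_hosts[gi_i])
                    gi_i += 1
                if t is None:
                    continue
                pools[kind] -= 1
                taken += 1
        for i, pair in enumerate(self.pair_loci):
            self.make_fusion(pair)
        for host in self.nested_hosts:
            self.make_antisense(host)
        for desert in self.deserts:
            self.make_intergenic(desert)
        # NMD designs: one exact copy of the full reference per dedicated gene
        n_pos, n_neg = cfg.nmd_quota
        for i, b in enumerate(self.nmd_genes):
            t = self._emit(
                "NMD", list(b.full_transcript.exons), b.gene.gene_id, "FSM"
            )
            self.truth.nmd[t.transcript_id] = i < n_pos
        # intrapriming designations: extend a slice of NIC/NNC queries
        novel = [
            t
            for t in self.queries
            if self.truth.category[t.transcript_id] in ("NIC", "NNC")
            and not self.truth.fragment[t.transcript_id]
        ]
        n_ip = int(round(cfg.intrapriming_fraction * len(novel)))
        picked = self.rng.choice(len(novel), size=n_ip, replace=False) if n_ip else []
        for i in picked:
            t = novel[int(i)]
            t.exons = _extend_3prime(t.exons, t.strand, cfg.intrapriming_extension)
            self.truth.intrapriming[t.transcript_id] = True

    # -- genome sequence ----------------------------------------------------

    def _register_window(self, chrom: str, start: int, seq: str) -> None:
        key = (chrom, start)
        prev = self._windows.get(key)
        if prev is not None:
            assert prev == (len(seq), seq), "conflicting window writes"
            return
        for (c, s), (ln, _) in self._windows.items():
            if c == chrom and s < start + len(seq) and start < s + ln:
                raise AssertionError("partially overlapping genome windows")
        self._windows[key] = (len(seq), seq)
        self._genome_writes.append((chrom, start, seq))

    def _design_orf_sequence(self, t: TranscriptModel, stop_before_junction: bool) -> str:
        """Transcript sequence whose single ATG-initiated ORF ends 60 nt
        up- or downstream of the last junction."""
        rng = self.rng
        L = t.length
        junction = t.junction_transcript_positions()[-1]
        s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=L)])
        # remove every ATG so the designed start is the only one
        while "ATG" in s:
            s = s.replace("ATG", "ACG")
        seq = list(s)
        stop_end = junction - 60 if stop_before_junction else junction + 60
        start = 30
        start += (stop_end - start) % 3
        assert start + 6 <= stop_end <= L, "transcript too short for ORF design"
        seq[start : start + 3] = "ATG"
        body = (stop_end - 3 - (start + 3)) // 3
        seq[start + 3 : stop_end - 3] = list("CTG" * body)
        seq[stop_end - 3 : stop_end] = "TAA"
        # the stop's trailing AA can recreate an ATG across the boundary
        if stop_end + 2 <= L and seq[stop_end] == "T" and seq[stop_end + 1] == "G":
            seq[stop_end + 1] = "C"
        out = "".join(seq)
        assert out.find("ATG") == start and out.find("ATG", start + 1) == -1
        return out

    def build_genome(self) -> SequenceStore:
        cfg, rng = self.cfg, self.rng
        # designed NMD/ORF sequences written exon-wise
        from Bio.Seq import reverse_complement

        for t in self.queries:
            if t.transcript_id in self.truth.nmd:
                s = self._design_orf_sequence(
                    t, stop_before_junction=self.truth.nmd[t.transcript_id]
                )
                pos = 0
                for exon in t.exons_transcription_order():
                    chunk = s[pos : pos + len(exon)]
                    pos += len(exon)
                    if t.strand == "-":
                        chunk = reverse_complement(chunk)
                    self._register_window(t.chrom, exon.start, chunk)
        # intrapriming tracts and scrub windows downstream of every 3' end
        for t in self.queries:
            ws, we = _downstream_window(t, 20)
            if self.truth.intrapriming[t.transcript_id]:
                tract = "A" * 20 if t.strand == "+" else "T" * 20
                self._register_window(t.chrom, ws, tract)
            else:
                self._register_window(t.chrom, ws, SCRUB_PATTERN)
        lengths = {c: self.cursors[c] + 1000 for c in self.cursors}
        chroms = {}
        for chrom in sorted(lengths):
            n = lengths[chrom]
            arr = rng.choice(BASES, size=n)
            chroms[chrom] = arr
        for chrom, start, seq in self._genome_writes:
            chroms[chrom][start : start + len(seq)] = np.frombuffer(
                seq.encode(), dtype="S1"
            )
        return SequenceStore(
            {c: a.tobytes().decode() for c, a in chroms.items()}
        )

    def build_cage(self) -> list[GenomicInterval]:
        cfg, rng = self.cfg, self.rng
        peaks = []
        seen = set()
        for b in self.all_builds:
            for t in b.gene.transcripts:
                center = t.tss + int(round(rng.normal(0, cfg.cage_jitter_sd)))
                s = center - cfg.cage_peak_width // 2
                key = (t.chrom, s)
                if key in seen:
                    continue
                seen.add(key)
                peaks.append(
                    GenomicInterval(t.chrom, s, s + cfg.cage_peak_width, t.strand)
                )
        return sorted(peaks, key=lambda p: (p.chrom, p.start))


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_counts(
    config: SimulationConfig,
    queries: Sequence[TranscriptModel],
    truth: TruthSet,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial full-length counts per transcript per sample.

    Columns are sample-and-cell combinations for the two groups; DTU genes
    (two multi-exonic transcripts with swapped group means) are planted
    and recorded in the truth set.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    na, nb = config.samples_per_group
    ga, gb = config.group_names
    cols = [
        f"{g}_s{i + 1}c{c + 1}"
        for g, n in ((ga, na), (gb, nb))
        for i in range(n)
        for c in range(config.cells_per_sample)
    ]
    group_map = pd.Series(
        {c: (ga if c.startswith(ga) else gb) for c in cols}, name="group"
    )
    n_a_cols = na * config.cells_per_sample

    by_gene: dict[str, list[str]] = {}
    for t in queries:
        tid = t.transcript_id
        gid = truth.gene.get(tid)
        if (
            gid is not None
            and t.n_exons > 1
            and not truth.fragment[tid]
            and not truth.intrapriming[tid]
            and tid not in truth.nmd
        ):
            by_gene.setdefault(gid, []).append(tid)
    candidates = sorted(g for g, ts in by_gene.items() if len(ts) >= 2)
    n_dtu = min(config.dtu_gene_quota, len(candidates))
    dtu_pick = (
        [candidates[int(i)] for i in rng.choice(len(candidates), n_dtu, replace=False)]
        if n_dtu
        else []
    )
    hi, lo = config.dtu_means
    rows = {}
    for t in queries:
        base = float(
            np.exp(rng.uniform(np.log(config.nb_mean_range[0]), np.log(config.nb_mean_range[1])))
        )
        rows[t.transcript_id] = np.concatenate(
            [
                _nb_draw(rng, base, config.nb_dispersion, n_a_cols),
                _nb_draw(rng, base, config.nb_dispersion, len(cols) - n_a_cols),
            ]
        )
    for gid in dtu_pick:
        t_up_a, t_up_b = by_gene[gid][0], by_gene[gid][1]
        rows[t_up_a] = np.concatenate(
            [
                _nb_draw(rng, hi, config.nb_dispersion, n_a_cols),
                _nb_draw(rng, lo, config.nb_dispersion, len(cols) - n_a_cols),
            ]
        )
        rows[t_up_b] = np.concatenate(
            [
                _nb_draw(rng, lo, config.nb_dispersion, n_a_cols),
                _nb_draw(rng, hi, config.nb_dispersion, len(cols) - n_a_cols),
            ]
        )
        truth.dtu_genes[gid] = (t_up_a, t_up_b)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    counts.index.name = "transcript_id"
    return counts, group_map


def simulate_switch_counts(
    seed: int,
    n_genes: int = 50,
    mean_high: float = 60.0,
    mean_low: float = 5.0,
    dispersion: float = 0.3,
    samples_per_group: tuple[int, int] = (4, 3),
    cells_per_sample: int = 2,
    n_background: int = 500,
    background_mean: float | None = None,
    null: bool = False,
) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Counts matrix with planted two-transcript isoform switches.

    Background transcripts pad the per-sample totals to ~10^6 reads so
    that TPM values sit on the same scale as the planted count means.
    With ``null=True`` the two groups share every mean (no switch), for
    calibration checks.
    Returns (counts, sample->group mapping, transcript->gene mapping).
    """
    rng = np.random.default_rng(seed)
    na, nb = samples_per_group
    cols = [
        f"{g}_s{i + 1}c{c + 1}"
        for g, n in (("A", na), ("B", nb))
        for i in range(n)
        for c in range(cells_per_sample)
    ]
    n_a = na * cells_per_sample
    n_b = nb * cells_per_sample
    if background_mean is None:
        signal = n_genes * (mean_high + mean_low)
        background_mean = max((1e6 - signal) / max(n_background, 1), 1.0)
    rows, gene_map = {}, {}
    for g in range(n_genes):
        gid = f"g{g + 1}"
        for k, (ma, mb) in enumerate(
            [(mean_high, mean_low), (mean_low, mean_high)]
        ):
            if null:
                ma = mb = mean_high if k == 0 else mean_low
            tid = f"{gid}.t{k + 1}"
            gene_map[tid] = gid
            rows[tid] = np.concatenate(
                [
                    _nb_draw(rng, ma, dispersion, n_a),
                    _nb_draw(rng, mb, dispersion, n_b),
                ]
            )
    for i in range(n_background):
        tid = f"bg.t{i + 1}"
        gene_map[tid] = f"bg{i + 1}"
        rows[tid] = _nb_draw(rng, background_mean, dispersion, n_a + n_b)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    counts.index.name = "transcript_id"
    groups = pd.Series({c: c[0] for c in cols}, name="group")
    return counts, groups, gene_map


# ---------------------------------------------------------------------------
# top-level API


def simulate_reference(config: SimulationConfig) -> _Simulator:
    """Build the reference layer (genes, variants, loci); returns the
    simulator carrying the layout for the query phase."""
    sim = _Simulator(config)
    sim.build_reference()
    return sim


def simulate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the full dataset: genome, annotation, queries, truth,
    CAGE peaks and counts.  Byte-deterministic under the config seed."""
    config = config or SimulationConfig()
    sim = simulate_reference(config)
    sim.build_queries()
    genome = sim.build_genome()
    cage = sim.build_cage()
    annotation = sim.annotation()
    counts, groups = simulate_counts(config, sim.queries, sim.truth)
    return SyntheticDataset(
        config=config,
        genome=genome,
        annotation=annotation,
        reference_transcripts=list(annotation.transcripts.values()),
        queries=sim.queries,
        truth=sim.truth,
        cage_peaks=cage,
        counts=counts,
        groups=groups,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as standard files (FASTA/GTF/BED/TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_gtf": outdir / "reference.gtf",
        "query_gtf": outdir / "queries.gtf",
        "genome_fasta": outdir / "genome.fa",
        "cage_bed": outdir / "cage.bed",
        "counts_tsv": outdir / "counts.tsv",
        "groups_tsv": outdir / "groups.tsv",
        "truth_tsv": outdir / "truth.tsv",
    }
    ref_ts = [t for g in ds.annotation.genes.values() for t in g.transcripts]
    write_gtf(ref_ts, paths["reference_gtf"])
    write_gtf(ds.queries, paths["query_gtf"])
    with open(paths["genome_fasta"], "w") as fh:
        for chrom in ds.genome.chroms():
            fh.write(f">{chrom}\n")
            seq = ds.genome.fetch(chrom, 0, ds.genome.length(chrom))
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(paths["cage_bed"], "w") as fh:
        for p in ds.cage_peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tcage\t0\t{p.strand}\n")
    if ds.counts is not None:
        ds.counts.to_csv(paths["counts_tsv"], sep="\t")
        ds.groups.to_csv(paths["groups_tsv"], sep="\t", header=False)
    truth_rows = []
    for t in ds.queries:
        tid = t.transcript_id
        truth_rows.append(
            {
                "transcript_id": tid,
                "category": ds.truth.category[tid],
                "gene": ds.truth.gene.get(tid, ""),
                "ir": ds.truth.ir[tid],
                "nmd": ds.truth.nmd.get(tid, ""),
                "fragment": ds.truth.fragment[tid],
                "intrapriming": ds.truth.intrapriming[tid],
            }
        )
    pd.DataFrame(truth_rows).to_csv(paths["truth_tsv"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# small constructive generators used for oracle-equivalence testing


def random_gene_transcripts(
    rng: np.random.Generator,
    n_transcripts: int = 4,
    chrom: str = "chrS",
    origin: int = 1000,
) -> list[TranscriptModel]:
    """A random multi-transcript gene built from a shared site pool with
    random skips, terminal-exon swaps and splice-site shifts (for
    pairwise-event and classifier oracle checks)."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(3, 7))
    exons = []
    pos = origin
    for _ in range(n_exons):
        ln = int(rng.integers(80, 200))
        exons.append((pos, pos + ln))
        pos += ln + int(rng.integers(100, 300))
    out = []
    for i in range(n_transcripts):
        evs = [list(e) for e in exons]
        # random structural edits
        if n_exons >= 4 and rng.random() < 0.5:
            j = int(rng.integers(1, n_exons - 1))
            evs = evs[:j] + evs[j + 1 :]
        if rng.random() < 0.4 and len(evs) >= 2:
            # shift an internal boundary (A5/A3 material)
            j = int(rng.integers(0, len(evs) - 1))
            delta = int(rng.integers(-40, 41))
            if evs[j][1] - delta - evs[j][0] >= 40 and delta < 80:
                evs[j][1] -= delta
        if rng.random() < 0.4:
            # alternative first exon (genomic left), non-overlapping
            ln = int(rng.integers(60, 140))
            gap = int(rng.integers(20, 120))
            evs[0] = [evs[0][0] - gap - ln, evs[0][0] - gap]
        ivs = [GenomicInterval(chrom, s, e, strand) for s, e in evs]
        out.append(TranscriptModel(f"rt{i + 1}", "geneR", chrom, strand, ivs))
    return out
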