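"""Structural classification, artifact filters and evidence annotators."""

import numpy as np
import pytest

from isokit import classify
from isokit.models import (
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    SequenceStore,
)

from _oracles import oracle_classify
from conftest import make_transcript as tm


def small_reference():
    """One gene, three exons, with a skip variant; plus a mono-exonic gene."""
    r1 = tm("R1", "+", [(100, 200), (300, 400), (500, 600)], gene_id="G1")
    r2 = tm("R2", "+", [(100, 200), (500, 600)], gene_id="G1")
    mono = tm("R3", "+", [(5000, 5500)], gene_id="G2")
    return GenomeAnnotation(
        [
            Gene("G1", "chr1", "+", 100, 600, [r1, r2]),
            Gene("G2", "chr1", "+", 5000, 5500, [mono]),
        ]
    )


class TestCategories:
    def test_identical_chain_is_fsm(self):
        ref = small_reference()
        t = tm("q", "+", [(90, 200), (300, 400), (500, 650)])
        rec = classify.classify_transcript(t, ref)
        assert rec.category == "FSM"
        assert rec.associated_transcript == "R1"
        assert rec.associated_genes == ["G1"]
        assert not rec.novel_flag

    def test_suffix_chain_is_ism_5prime(self):
        ref = small_reference()
        t = tm("q", "+", [(320, 400), (500, 600)])
        rec = classify.classify_transcript(t, ref)
        assert rec.category == "ISM"
        assert rec.associated_transcript == "R1"
        assert rec.ism_subtype == "5prime"
        # ISM counts as known, not novel
        assert not rec.novel_flag
        assert rec.category in classify.KNOWN_CATEGORIES

    def test_known_site_recombination_is_nic(self):
        # retaining an interior intron keeps every splice site annotated
        # but yields a chain no reference carries (and is not a contiguous
        # sub-chain of one): NIC with the retained intron flagged
        r = tm("R1", "+", [(0, 100), (200, 300), (400, 500), (600, 700)], gene_id="G1")
        ref = GenomeAnnotation([Gene("G1", "chr1", "+", 0, 700, [r])])
        t = tm("q", "+", [(0, 100), (200, 500), (600, 700)])  # merges exons 2+3
        rec = classify.classify_transcript(t, ref)
        assert rec.category == "NIC"
        assert rec.ir_flag
        assert rec.ir_introns == [(300, 400)]

    def test_novel_site_is_nnc(self):
        ref = small_reference()
        t = tm("q", "+", [(100, 200), (310, 400), (500, 600)])
        rec = classify.classify_transcript(t, ref)
        assert rec.category == "NNC"

    def test_monoexonic_contained_in_mono_reference_is_fsm(self):
        ref = small_reference()
        t = tm("q", "+", [(5100, 5400)])
        rec = classify.classify_transcript(t, ref)
        assert rec.category == "FSM"
        assert rec.associated_transcript == "R3"

    def test_monoexonic_spanning_exon_and_intron_is_genic_genomic(self):
        ref = small_reference()
        t = tm("q", "+", [(150, 250)])
        assert classify.classify_transcript(t, ref).category == "genic_genomic"

    def test_monoexonic_inside_intron_is_genic_intron(self):
        ref = small_reference()
        t = tm("q", "+", [(210, 290)])
        assert classify.classify_transcript(t, ref).category == "genic_intron"

    def test_opposite_strand_overlap_is_antisense(self):
        ref = small_reference()
        t = tm("q", "-", [(150, 250), (350, 450)])
        assert classify.classify_transcript(t, ref).category == "antisense"

    def test_no_overlap_is_intergenic(self):
        ref = small_reference()
        t = tm("q", "+", [(9000, 9100), (9200, 9300)])
        assert classify.classify_transcript(t, ref).category == "intergenic"

    def test_fusion_spans_disjoint_genes(self):
        ra = tm("RA", "+", [(100, 200), (300, 400)], gene_id="GA")
        rb = tm("RB", "+", [(1000, 1100), (1200, 1300)], gene_id="GB")
        ref = GenomeAnnotation(
            [
                Gene("GA", "chr1", "+", 100, 400, [ra]),
                Gene("GB", "chr1", "+", 1000, 1300, [rb]),
            ]
        )
        t = tm("q", "+", [(100, 200), (300, 400), (1000, 1100), (1200, 1300)])
        rec = classify.classify_transcript(t, ref)
        assert rec.category == "fusion"
        assert rec.associated_genes == ["GA", "GB"]

    def test_categories_partition_the_input(self, default_dataset):
        ds = default_dataset
        recs = classify.classify_all(ds.queries, ds.annotation)
        assert len(recs) == len(ds.queries)
        counts = {}
        for r in recs:
            counts[r.category] = counts.get(r.category, 0) + 1
        assert sum(counts.values()) == len(ds.queries)
        assert set(counts) <= set(classify.CATEGORIES)

    def test_classify_all_equals_per_transcript_calls(self, default_dataset):
        ds = default_dataset
        sample = ds.queries[::17]
        batch = classify.classify_all(sample, ds.annotation)
        single = [classify.classify_transcript(t, ds.annotation) for t in sample]
        assert [(r.category, r.associated_genes, r.associated_transcript) for r in batch] == [
            (r.category, r.associated_genes, r.associated_transcript) for r in single
        ]

    def test_empty_input_gives_empty_table(self):
        ref = small_reference()
        assert classify.classify_all([], ref) == []

    def test_agrees_with_bruteforce_oracle(self, default_dataset):
        ds = default_dataset
        for t in ds.queries:
            rec = classify.classify_transcript(t, ds.annotation)
            cat, genes, assoc = oracle_classify(t, ds.annotation)
            assert rec.category == cat, t.transcript_id
            assert set(rec.associated_genes) == genes, t.transcript_id
            assert rec.associated_transcript == assoc, t.transcript_id

    def test_ir_implies_novel_category(self, default_dataset):
        ds = default_dataset
        for r in classify.classify_all(ds.queries, ds.annotation):
            if r.ir_flag:
                assert r.category in ("NIC", "NNC", "fusion", "genic_genomic")


class TestFragmentFilter:
    def test_suffix_with_same_end_removed(self):
        u = tm("u", "+", [(0, 100), (200, 300), (400, 500), (600, 700)])
        t = tm("t", "+", [(250, 300), (400, 500), (600, 700)])
        rep = classify.remove_fragments([u, t])
        assert rep.removed_fragment_ids == ["t"]
        assert [x.transcript_id for x in rep.surviving] == ["u"]

    def test_transcript_with_unique_junction_retained(self):
        u = tm("u", "+", [(0, 100), (200, 300), (400, 500)])
        t = tm("t", "+", [(250, 310), (420, 500)])
        rep = classify.remove_fragments([u, t])
        assert rep.removed_fragment_ids == []

    def test_3prime_tolerance_gates_removal(self):
        u = tm("u", "+", [(0, 100), (200, 300), (400, 500)])
        near = tm("n", "+", [(250, 300), (400, 450)])  # 3' end 50 away
        far = tm("f", "+", [(250, 300), (400, 650)])  # 150 away
        rep = classify.remove_fragments([u, near, far])
        assert rep.removed_fragment_ids == ["n"]

    def test_monoexonic_contained_in_last_exon_removed(self):
        u = tm("u", "+", [(0, 100), (200, 500)])
        t = tm("t", "+", [(300, 480)])
        rep = classify.remove_fragments([u, t])
        assert rep.removed_fragment_ids == ["t"]

    def test_idempotent_on_random_sets(self):
        rng = np.random.default_rng(3)
        for trial in range(500):
            n = int(rng.integers(2, 7))
            ts = []
            # random chains drawn from a shared small junction pool
            pool = sorted(rng.choice(np.arange(100, 2000, 50), size=8, replace=False))
            for i in range(n):
                k = int(rng.integers(1, 4))
                start = int(rng.integers(0, len(pool) // 2))
                coords = pool[start : start + 2 * k]
                if len(coords) < 2 * k:
                    continue
                exons = [(int(coords[0]) - int(rng.integers(20, 80)), int(coords[0]))]
                for a, b in zip(coords[1::2], coords[2::2]):
                    exons.append((int(a), int(b)))
                exons.append((int(coords[-1]), int(coords[-1]) + int(rng.integers(20, 120))))
                merged = []
                for s, e in exons:
                    if merged and s <= merged[-1][1]:
                        merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
                    else:
                        merged.append((s, e))
                try:
                    ts.append(tm(f"t{trial}.{i}", "+", merged))
                except Exception:
                    continue
            once = classify.remove_fragments(ts)
            twice = classify.remove_fragments(once.surviving)
            assert twice.removed_fragment_ids == []

    def test_fsm_set_invariant_under_filter(self, default_dataset):
        ds = default_dataset
        before = {
            r.transcript_id
            for r in classify.classify_all(ds.queries, ds.annotation)
            if r.category == "FSM"
        }
        rep = classify.remove_fragments(ds.queries)
        after = {
            r.transcript_id
            for r in classify.classify_all(rep.surviving, ds.annotation)
            if r.category == "FSM"
        }
        assert before == after


class TestIntrapriming:
    def make_genome(self, downstream):
        return SequenceStore({"chr1": "C" * 100 + downstream + "C" * 50})

    def test_all_a_window_flagged(self):
        g = self.make_genome("A" * 20)
        t = tm("t", "+", [(50, 100)])
        frac, flag = classify.intrapriming_fraction(t, g)
        assert frac == 1.0 and flag

    def test_quarter_a_not_flagged(self):
        g = self.make_genome("ACGTACGTACGTACGTACGT")
        t = tm("t", "+", [(50, 100)])
        frac, flag = classify.intrapriming_fraction(t, g)
        assert frac == 0.25 and not flag

    def test_exactly_rate_point_six_flagged(self):
        g = self.make_genome("A" * 12 + "C" * 8)
        t = tm("t", "+", [(50, 100)])
        frac, flag = classify.intrapriming_fraction(t, g)
        assert frac == pytest.approx(0.6) and flag

    def test_minus_strand_counts_genomic_t(self):
        genome = SequenceStore({"chr1": "T" * 20 + "G" * 80})
        t = tm("t", "-", [(20, 80)])
        frac, flag = classify.intrapriming_fraction(t, genome)
        assert frac == 1.0 and flag

    def test_truncated_window_at_chromosome_end(self):
        genome = SequenceStore({"chr1": "C" * 50 + "AAAAA"})
        t = tm("t", "+", [(10, 50)])
        frac, flag = classify.intrapriming_fraction(t, genome)
        assert frac == 1.0  # 5 of the 5 available bases

    def test_filter_spares_fsm(self, default_dataset):
        ds = default_dataset
        recs = classify.classify_all(ds.queries, ds.annotation, genome=ds.genome)
        rep = classify.remove_intrapriming(ds.queries, recs)
        flagged_fsm = {
            r.transcript_id
            for r in recs
            if r.intrapriming_flag and r.category == "FSM"
        }
        assert flagged_fsm.isdisjoint(rep.removed_intrapriming_ids)


class TestPolyA:
    def test_motif_distance_from_3prime_end(self):
        seq = "C" * 30 + "AATAAA" + "G" * 16
        genome = SequenceStore({"chr1": seq})
        t = tm("t", "+", [(0, len(seq))])
        motif, dist = classify.polya_motif_scan(t, genome, ["AATAAA"])
        assert (motif, dist) == ("AATAAA", 16)

    def test_absent_motif_returns_none(self):
        genome = SequenceStore({"chr1": "C" * 60})
        t = tm("t", "+", [(0, 60)])
        assert classify.polya_motif_scan(t, genome, ["AATAAA"]) is None

    def test_closest_motif_wins_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        motifs = ["AATAAA", "ATTAAA", "AGTAAA"]
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=120))
            genome = SequenceStore({"chr1": seq})
            t = tm("t", "+", [(0, 120)])
            got = classify.polya_motif_scan(t, genome, motifs)
            # exhaustive: every motif occurrence in the last 50 nt
            tail = seq[-50:]
            hits = []
            for rank, m in enumerate(motifs):
                for i in range(len(tail) - len(m) + 1):
                    if tail[i : i + len(m)] == m:
                        hits.append((len(tail) - i - len(m), rank, m))
            expect = None if not hits else (min(hits)[2], min(hits)[0])
            assert got == expect


class TestCage:
    def peaks(self, *ivs):
        return [GenomicInterval("chr1", s, e, "+") for s, e in ivs]

    def test_upstream_peak_negative_on_plus(self):
        t = tm("t", "+", [(1000, 1500)])
        d, within = classify.cage_distance(t, self.peaks((980, 990)))
        assert d == -10 and within

    def test_tss_inside_peak_is_zero(self):
        t = tm("t", "+", [(1000, 1500)])
        d, within = classify.cage_distance(t, self.peaks((990, 1010)))
        assert d == 0 and within

    def test_upstream_peak_negative_on_minus(self):
        # minus-strand TSS at 500 (end-exclusive 501); a peak at higher
        # coordinates is upstream in transcription orientation
        t = tm("t", "-", [(100, 501)])
        d, within = classify.cage_distance(t, self.peaks((510, 520)))
        assert d == -10 and within

    def test_no_peak_on_chromosome_returns_none(self):
        t = tm("t", "+", [(1000, 1500)], chrom="chr9")
        assert classify.cage_distance(t, self.peaks((10, 20))) is None
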