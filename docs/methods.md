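# Methods

This note records the models, conventions and design choices behind
`isokit`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic benchmark does and does not
demonstrate.

## Coordinates and junction chains

All internal coordinates are 0-based half-open on the genomic forward
strand; GTF input/output converts at the boundary (BED needs no
conversion).  A transcript's splice junctions are stored as
(donor, acceptor) pairs in *transcription* order: the donor is the
intron boundary adjacent to the upstream exon on the transcript's
strand, so on the minus strand the donor coordinate exceeds the acceptor
and the junction list runs right-to-left along the genome.  Writing the
event and classification rules on this strand-free axis means every rule
is implemented once.

Junction matching is exact everywhere.  No wobble window is applied to
donors or acceptors; the only positional tolerance in the pipeline is
the fragment filter's 3'-end tolerance (below).  This makes chain
comparison a pure dictionary lookup and keeps category assignment
deterministic.

## Structural classification

Categories are assigned in a fixed precedence order — FSM > ISM >
fusion > NIC > NNC > genic_genomic > genic_intron > antisense >
intergenic — which makes them mutually exclusive and exhaustive.  The
individual rules:

- Candidate genes are the same-strand genes with ≥ 1 bp of exonic
  overlap with the query.
- **FSM**: junction chain equal to a reference transcript's chain.  When
  several references match (possible only if they share a chain), the
  one minimizing |ΔTSS| + |ΔTTS| wins, ties broken by lexicographic
  transcript id.
- **ISM**: chain is a contiguous proper sub-chain of a reference chain,
  anchored anywhere.  The record carries a subtype: `5prime`
  (3'-anchored suffix, i.e. a 5'-truncation), `3prime` (prefix) or
  `internal`.  Whether 3' and internal fragments should count as ISM at
  all is genuinely ambiguous in the field's usage; we include them and
  expose the subtype so either reading can be recovered downstream.
- **fusion**: exonic overlap with ≥ 2 candidate genes whose annotated
  extents are pairwise disjoint — read-through over adjacent loci.
  Nested or overlapping gene pairs never trigger fusion; their site
  pools are merged instead.
- **NIC / NNC**: NIC requires every donor and every acceptor of the
  query to appear in the pooled site index of its candidate genes
  (pooling makes NIC monotone in annotation richness); NNC requires at
  least one unannotated site but at least one shared site or junction.
- **genic_genomic** covers exonic overlap with no shared splice
  evidence; **genic_intron** full containment in an annotated intron on
  the same strand; **antisense** overlap with annotation only on the
  opposite strand; **intergenic** everything else.
- Mono-exonic queries are FSM only when contained within a mono-exonic
  reference transcript of an overlapping gene, with zero boundary
  tolerance (no wobble is stated anywhere, so none is invented);
  otherwise they fall through to the non-spliced categories.

Intron retention (`ir_flag`) is recorded when an exon of the query
strictly contains both boundaries of an annotated intron of an
associated gene.  An exact FSM cannot retain an intron of its matched
transcript, so IR co-occurs with the novel categories; this is asserted
on generator data rather than assumed.

### Artifact filters

**Fragment filter.**  A transcript is removed when its chain is a
contiguous proper suffix (transcription order) of another *input*
transcript's chain and their 3' ends differ by at most Δ3 = 100 nt
(`--frag-3prime-tol`); a mono-exonic model is removed when contained in
another model's 3'-terminal exon under the same end tolerance.  The
witness set is the full input, not the surviving set, which makes the
filter idempotent (a survivor cannot lose its witness).  The 100 nt
default is a package choice: large enough to absorb polyA-site
heterogeneity, small enough not to merge genuinely distinct 3' ends.

**Intrapriming filter.**  The fraction of adenines (transcript strand)
in the 20 genomic bases downstream of the 3' end is computed; a fraction
≥ 0.6 flags the model, and flagged models are removed unless they are
FSM — annotated 3' ends are independently supported, and the filter
targets artifacts, not known transcripts.  The ≥ convention at exactly
0.6 is asserted in tests.

### Evidence annotations

CAGE distance is measured from the TSS (first transcribed base) to the
nearest peak edge, 0 inside a peak, negative when the peak lies upstream
in transcription orientation; `within_cage_50` uses |d| ≤ 50 bp.  PolyA
motifs are scanned in the final 50 nt of the transcript sequence and the
motif ending closest to the 3' terminus is reported, ties resolved by
motif list order.  The lncRNA flag is driven by a user-supplied gene-id
list rather than a hardcoded biotype set, since annotation releases
differ in which `gene_type` values count as long non-coding.

## AS events

Events are defined pairwise between a gene's multi-exonic transcripts
and deduplicated by a type-specific coordinate key; supporting
inclusion/exclusion transcript lists accumulate across pairs.  SE keys
are (d1,a1,d2,a2); MX requires identical flanking donor/acceptor and
strictly non-overlapping middle exons; A5/A3 require the inter-site
segment to be exonic in the transcript carrying the inner site; AF/AL
require non-overlapping first/last exons whose flanking junctions share
the downstream acceptor (AF) or upstream donor (AL) — the SUPPA-style
local-event convention.  An A5/A3 at the outermost junction pair that is
already explained by an AF/AL key is suppressed.  IR events are not
called pairwise: they come from the classification against the reference
annotation, keyed by retained intron.  Per-gene summaries report counts
by type and the predominant type (argmax of event counts, ties broken by
the fixed order AF > SE > A3 > A5 > AL > MX > IR; event counts rather
than transcript counts are used, a deliberate reading of "predominant").

Gene-level grouping takes the first associated gene from classification;
transcripts without one (novel antisense/intergenic genes) are clustered
by extent overlap per chromosome and strand.

## ORF, coding potential, NMD

The ORF finder scans the three forward frames (transcripts are
orientation-resolved upstream) for ATG…stop spans without internal
stops, reports the longest, and breaks ties to the 5'-most start.  The
reported span includes the stop codon; the protein length excludes it
(orf_length ≡ 0 mod 3, protein = orf/3 − 1).  Codons containing N never
act as start or stop, but an N inside an otherwise clean span does not
terminate it.

Coding potential defaults to the Fickett TESTCODE statistic computed
from the published position/composition lookup tables.  This is a
transparent, training-free statistic — not a logistic coding-probability
model — so the score distribution differs from CPAT-style
probabilities; the score source is recorded in the output, and the
conventional cutoffs (human ≥ 0.364 inclusive, mouse > 0.44 strict) are
meant for externally supplied probability tables, which take precedence
when given.  On random-sequence transcripts the Fickett statistic with
the 0.364 default flags nearly everything as coding; with real
transcript sequence or external CPAT scores the flag is informative.

NMD is predicted when a transcript has an ORF whose stop codon ends more
than `min_dist` nt upstream of the last exon–exon junction (transcript
coordinates).  The default is `min_dist = 0` — any stop strictly before
the last junction — with the canonical 50-nt rule available via
`--nmd-min-dist 50`; the stricter reading is not silently imposed.
Mono-exonic transcripts are never flagged.

## Expression, DTE, DTU

TPM is count divided by the per-sample total, × 10⁶, so every column
sums to one million (asserted to 1e-6 relative).  Gene-level expression
is the sum of member transcript counts with mono-exonic transcripts
removed by default and fusion transcripts always excluded (they have no
single gene).  Isoform-diversity statistics use the representative
longest transcript for gene length and exon count, Pearson correlation
(Spearman behavior can be obtained by ranking upstream), and a
log10 TPM > 2.5 threshold for the "highly expressed" stratum.

The DTE test is a two-sided Wilcoxon rank-sum on TPM: exact null
distribution when the pooled sample is ≤ 20 values without ties, else
mid-rank normal approximation with continuity correction.  Exactness
matters at this scale — the study design behind the defaults has 4 vs 3
donors, where approximations are unreliable.

DTU between replicated groups calls a gene when two transcripts are
significant (p < 0.05, no multiple-testing correction by design —
an optional BH step exists but defaults off to keep the printed rule) in
opposite directions, each with |Δ mean TPM| > 20.  "Exclusive
expression" is operationalized as opposite-direction significance; the
literal reading (detected in only one group) is available separately as
`group_specific_transcripts` (detection mode, or mean TPM > 20 in
exactly one group).  The unreplicated region rule flags a transcript at
fold change ≥ 4 (pseudocount 1 TPM on both means, so zero means are
well-defined; the Δ-TPM gate is unaffected) and |Δ| > 20 TPM, and calls
a gene on two opposite-direction flags.

Rarefaction samples reads without replacement at each depth (seeded)
and reports mean unique transcripts/genes; the Monte-Carlo mean is
checked against the hypergeometric closed form
Σᵢ [1 − C(N−nᵢ,d)/C(N,d)].

Cross-dataset comparison joins per-gene isoform counts through a
homolog map (non-unique mappings dropped), reports Pearson correlation,
and ranks divergent genes by absolute difference |a−b| and relative
difference max(a,b)/max(min(a,b),1).

## The synthetic benchmark

The generator emulates the statistical structure of a two-group
long-read cortex experiment at desk scale.  Defaults: three chromosomes;
~180 plain genes of 4–8 exons (exons 100–250 nt, terminal exons ≥ 180 nt,
introns 150–400 nt), each with 2–4 reference transcripts sharing a site
pool (full chain plus skip/alternative-first-exon variants); dedicated
adjacent same-strand gene pairs for fusion, host genes for antisense,
gene deserts for intergenic models.  Planted queries per category
(FSM 220, ISM 60, NIC 120, NNC 45, 6 each of the minor categories),
20 retained-intron models, 10+10 NMD designs, 15 degradation fragments
and ~10% intraprimed novel models.  Counts are negative binomial
(var = μ + 0.3 μ²) over 4 + 3 donors × 2 SMRT cells per donor — the
count columns are donor-and-cell combinations, matching how full-length
reads are tallied per cell — with five planted two-transcript isoform
switches at 60 ↔ 5 mean TPM.

Constructions are arranged so that every planted label is unambiguous
under the pipeline's own exact-matching semantics: ISM models shift
their 3' ends 150 nt (beyond the fragment tolerance) so they are not
eaten by the fragment filter; fragments keep their parent's 3' end so
they are; intraprimed models extend their 3' exon 200 nt so their
A-tract window is private; every non-intraprimed 3' end has its
downstream 20-mer rewritten to a fixed 25% A pattern; NMD designs are
the only ATG on their transcript, with the stop placed 60 nt up- or
downstream of the last junction, on genes hosting no other query.  A
rejection check (capped) guards the few random draws that could
otherwise collide with an annotated chain or site.

What passing on this benchmark shows: the implementation agrees with
the written rules — category assignment matches a brute-force oracle,
planted labels are recovered exactly, event catalogs equal the pairwise
definitions, the DTU rule has the intended power and calibration at the
study's design size.  What it does not show: robustness to alignment
wobble at splice sites, degraded/truncated reads beyond clean suffix
fragments, polyA-site scatter, paralogy, or realistic codon/hexamer
structure in coding sequence (non-designed transcript sequence is
uniform random DNA, which is why the Fickett flag saturates there).
Claims about real data rest on the rules themselves, which follow the
field's established conventions.

## Numerical and output conventions

Problem sizes in the tests and acceptance script (≈ 500–1,100 query
transcripts, 300-gene oracle sweeps, 20-seed DTU batches, 300-replicate
rarefaction) are chosen so the whole suite runs in well under an hour on
one CPU while keeping Monte-Carlo tolerances tight (3 standard errors).
All randomness flows from explicit seeds; reruns are byte-identical,
and the events TSV is written in a stable sort order to guarantee it.
Browser-track colors default to FSM blue (0,0,255), ISM cyan
(0,255,255), NIC red (255,0,0), NNC orange (255,165,0), others gray —
published figure legends disagree on the red/orange assignment of
NIC/NNC, so the palette is configurable.  Degenerate inputs error
early and by name: zero-total count columns, depth beyond the read
total, groups with fewer than two samples for the exact test,
correlations on fewer than three genes or constant vectors return
absent rather than NaN.

## Known limitations

ISM subtype semantics (whether internal fragments belong in ISM), the
predominant-event convention, and the NMD distance threshold are
documented choices, not ground truth.  The fragment filter is
witness-based and exact on junction chains; it will not remove
fragments whose junctions wobble.  Fickett scores are not CPAT
probabilities.  The homolog join keeps only one-to-one mappings and
drops the rest.  Single-cell and read-level error modeling are out of
scope.
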