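"""ORF prediction, coding-potential scoring and NMD prediction.

The ORF finder scans the three forward frames of the (already
orientation-resolved) transcript sequence for the longest ATG-initiated
open reading frame ending in a stop codon, the stop included.  Coding
potential defaults to the Fickett TESTCODE statistic computed from the
published position/composition lookup tables; an external per-transcript
probability table (e.g. from a logistic coding-potential model) can be
supplied instead and then takes precedence, with the usual species
cutoffs (human >= 0.364, mouse > 0.44) applied to those probabilities.

A transcript is predicted as an NMD (nonsense-mediated decay) target when
its ORF stop codon ends upstream of the last exon-exon junction; the
junction-to-stop distance threshold defaults to 0 nt and can be raised to
50 to apply the canonical 50-nt rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .models import SequenceStore, TranscriptModel, transcript_sequence

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

DEFAULT_CODING_CUTOFF = 0.364  # human cutoff, inclusive
MOUSE_CODING_CUTOFF = 0.44  # mouse cutoff, strict


@dataclass
class OrfPrediction:
    transcript_id: str
    has_orf: bool
    orf_start: int | None = None  # transcript coords, 0-based
    orf_end: int | None = None  # half-open, stop codon included
    orf_length: int = 0
    protein_length: int = 0
    stop_to_last_junction: int | None = None  # >0: stop upstream of junction
    nmd_flag: bool = False
    coding_score: float | None = None
    coding_flag: bool = False
    score_source: str = "fickett"


def find_orf(seq: str, transcript_id: str = "") -> OrfPrediction:
    """Longest ATG...stop ORF over the three forward frames.

    The reported span includes the stop codon, so orf_length is a multiple
    of three and protein_length = orf_length/3 - 1.  Length ties resolve
    to the 5'-most start.  Codons containing N never act as start or stop.
    """
    seq = seq.upper()
    best: tuple[int, int] | None = None  # (-length, start)
    best_span: tuple[int, int] | None = None
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                cand = (-(pos + 3 - start), start)
                if best is None or cand < best:
                    best = cand
                    best_span = (start, pos + 3)
                start = None
    if best_span is None:
        return OrfPrediction(transcript_id, has_orf=False)
    s, e = best_span
    return OrfPrediction(
        transcript_id,
        has_orf=True,
        orf_start=s,
        orf_end=e,
        orf_length=e - s,
        protein_length=(e - s) // 3 - 1,
    )


# ---------------------------------------------------------------------------
# Fickett TESTCODE
#
# Position and content parameters from Fickett (1982), Nucleic Acids Res.
# 10:5303-5318: for each base, the periodicity of its occurrence over the
# three codon positions and its overall fraction are each converted to a
# probability-of-coding via a lookup table and combined with fixed weights.

_POSITION_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0]


def _lookup(value: float, para: list[float], prob: list[float]) -> float:
    for threshold, p in zip(para, prob):
        if value >= threshold:
            return p
    return prob[-1]


def fickett_score(seq: str) -> float | None:
    """Fickett TESTCODE statistic of a DNA sequence (None below 2 codons)."""
    seq = seq.upper()
    if len(seq) < 6:
        return None
    total = 0.0
    counts_by_pos = {b: [0, 0, 0] for b in "ACGT"}
    for i, base in enumerate(seq):
        if base in counts_by_pos:
            counts_by_pos[base][i % 3] += 1
    n_acgt = sum(sum(c) for c in counts_by_pos.values())
    if n_acgt == 0:
        return None
    for base in "ACGT":
        c = counts_by_pos[base]
        position_value = max(c) / (min(c) + 1)
        content_value = sum(c) / n_acgt
        total += (
            _lookup(position_value, _POSITION_PARA, _POSITION_PROB[base])
            * _POSITION_WEIGHT[base]
        )
        total += (
            _lookup(content_value, _CONTENT_PARA, _CONTENT_PROB[base])
            * _CONTENT_WEIGHT[base]
        )
    return total


def coding_call(
    score: float | None,
    cutoff: float = DEFAULT_CODING_CUTOFF,
    strict: bool = False,
) -> bool:
    """Coding flag from a score: score >= cutoff, or > cutoff when
    ``strict`` (the mouse convention)."""
    if score is None:
        return False
    return score > cutoff if strict else score >= cutoff


def nmd_flag(
    t: TranscriptModel, orf: OrfPrediction, min_dist: int = 0
) -> bool:
    """NMD prediction: ORF present and the stop codon ends more than
    ``min_dist`` nt upstream of the last exon-exon junction.  Mono-exonic
    transcripts are never flagged."""
    if not orf.has_orf or t.is_monoexonic:
        return False
    last_junction = t.junction_transcript_positions()[-1]
    return (last_junction - orf.orf_end) > min_dist


def annotate_orfs(
    transcripts: Sequence[TranscriptModel],
    genome: SequenceStore,
    coding_cutoff: float = DEFAULT_CODING_CUTOFF,
    strict_cutoff: bool = False,
    external_scores: Mapping[str, float] | None = None,
    nmd_min_dist: int = 0,
) -> list[OrfPrediction]:
    """ORF + coding + NMD annotation for a batch of transcripts.

    When ``external_scores`` supplies a probability for a transcript it
    takes precedence over the built-in Fickett statistic and its source is
    recorded in the prediction.
    """
    out = []
    for t in transcripts:
        seq = transcript_sequence(t, genome)
        orf = find_orf(seq, t.transcript_id)
        if external_scores is not None and t.transcript_id in external_scores:
            orf.coding_score = external_scores[t.transcript_id]
            orf.score_source = "external"
        else:
            orf.coding_score = fickett_score(seq)
        orf.coding_flag = coding_call(orf.coding_score, coding_cutoff, strict_cutoff)
        if orf.has_orf and not t.is_monoexonic:
            last_junction = t.junction_transcript_positions()[-1]
            orf.stop_to_last_junction = last_junction - orf.orf_end
            orf.nmd_flag = orf.stop_to_last_junction > nmd_min_dist
        out.append(orf)
    return out


def orf_table(predictions: Sequence[OrfPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [p.transcript_id for p in predictions],
            "has_orf": [p.has_orf for p in predictions],
            "orf_start": [p.orf_start for p in predictions],
            "orf_end": [p.orf_end for p in predictions],
            "orf_length": [p.orf_length for p in predictions],
            "protein_length": [p.protein_length for p in predictions],
            "stop_to_last_junction": [p.stop_to_last_junction for p in predictions],
            "coding_score": [p.coding_score for p in predictions],
            "coding_flag": [p.coding_flag for p in predictions],
            "nmd_flag": [p.nmd_flag for p in predictions],
            "score_source": [p.score_source for p in predictions],
        }
    )
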