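"""Coding/noncoding partition of assembled transcripts.

A transcript is called coding when it carries an open reading frame longer
than 50 amino acids whose translation hits a reference protein set; every
other transcript is a noncoding candidate. lncRNA candidates are then the
noncoding transcripts between 200 and 1800 nt (inclusive). The homology
gate accepts either a precomputed hit table (so results of an external
protein search can be injected) or a reference protein set scored with a
built-in Smith-Waterman/BLOSUM62 aligner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .seqio import TranscriptRecord, reverse_complement

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfResult:
    """One ATG..stop open reading frame, in forward-strand coordinates.

    ``start``/``end`` are 0-based half-open on the forward strand and span
    ATG through the stop codon inclusive; ``aa_length`` excludes the stop.
    """

    transcript_id: str
    frame: int
    strand: str
    start: int
    end: int
    protein: str
    aa_length: int


def find_orfs(
    transcript: TranscriptRecord | tuple[str, str],
    min_aa: int = 50,
    both_strands: bool = True,
) -> list[OrfResult]:
    """All ORFs with ``aa_length`` strictly greater than ``min_aa``.

    Every ATG opens a candidate that closes at the first in-frame stop
    (ORFs without a stop are discarded); all six frames are scanned unless
    ``both_strands`` is False. Sorted by aa_length descending, ties by
    (strand, start) ascending.
    """
    if isinstance(transcript, tuple):
        tid, seq = transcript
    else:
        tid, seq = transcript.id, transcript.sequence
    n = len(seq)
    results: list[OrfResult] = []
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", reverse_complement(seq)))
    for strand, s in strands:
        for frame in range(3):
            results.extend(_scan_frame(tid, s, frame, strand, n, min_aa))
    results.sort(key=lambda o: (-o.aa_length, o.strand, o.start))
    return results


def _scan_frame(
    tid: str, s: str, frame: int, strand: str, n: int, min_aa: int
) -> list[OrfResult]:
    codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
    # First in-frame stop at or after each codon index.
    next_stop = [len(codons)] * (len(codons) + 1)
    for i in range(len(codons) - 1, -1, -1):
        next_stop[i] = i if codons[i] in STOP_CODONS else next_stop[i + 1]
    out = []
    for i, codon in enumerate(codons):
        if codon != "ATG":
            continue
        j = next_stop[i]
        if j >= len(codons):
            continue  # open-ended: no stop, discarded
        aa_len = j - i  # ATG..stop spans j-i+1 codons, stop excluded
        if aa_len <= min_aa:
            continue
        s_start = frame + 3 * i
        s_end = frame + 3 * (j + 1)
        if strand == "+":
            start, end = s_start, s_end
        else:
            start, end = n - s_end, n - s_start
        protein = str(Seq(s[s_start : s_end - 3]).translate())
        out.append(OrfResult(tid, frame, strand, start, end, protein, aa_len))
    return out


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def homology_hit(
    protein_query: str,
    reference_proteins: Sequence[str],
    score_threshold: float = 60.0,
) -> bool:
    """True when a Smith-Waterman/BLOSUM62 local alignment (gap open 11,
    extend 1) against any reference protein reaches ``score_threshold``."""
    if not protein_query:
        raise ValueError("empty protein query")
    if not reference_proteins:
        return False
    aligner = _protein_aligner()
    query = protein_query.replace("*", "X")
    for ref in reference_proteins:
        if not ref:
            continue
        if aligner.score(ref.replace("*", "X"), query) >= score_threshold:
            return True
    return False


def classify_transcripts(
    transcripts: Iterable[TranscriptRecord],
    homology_gate: Mapping[str, bool] | Sequence[str],
    min_aa: int = 50,
    score_threshold: float = 60.0,
    both_strands: bool = True,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Partition transcripts into ``(coding, noncoding)``.

    ``homology_gate`` is either a mapping ``transcript id -> has_hit`` (hit
    table mode, the default route for injecting external search results) or
    a sequence of reference proteins scored with :func:`homology_hit`.
    Coding requires both an ORF longer than ``min_aa`` amino acids and a
    gate hit; the partition is exhaustive and disjoint.
    """
    table_mode = isinstance(homology_gate, Mapping)
    if not table_mode and len(homology_gate) == 0:
        warnings.warn("empty reference protein set: all transcripts noncoding")
    coding: list[TranscriptRecord] = []
    noncoding: list[TranscriptRecord] = []
    aligner = None if table_mode else _protein_aligner()
    refs = None if table_mode else [r.replace("*", "X") for r in homology_gate if r]
    for t in transcripts:
        orfs = find_orfs(t, min_aa=min_aa, both_strands=both_strands)
        is_coding = False
        if orfs:
            if table_mode:
                is_coding = bool(homology_gate.get(t.id, False))
            elif refs:
                for orf in orfs:  # longest first: cheap short-circuit
                    q = orf.protein.replace("*", "X")
                    if any(aligner.score(r, q) >= score_threshold for r in refs):
                        is_coding = True
                        break
        (coding if is_coding else noncoding).append(t)
    return coding, noncoding


def filter_lncrna_candidates(
    noncoding: Iterable[TranscriptRecord],
    min_len: int = 200,
    max_len: int = 1800,
) -> list[TranscriptRecord]:
    """Length gate for lncRNA candidates, inclusive at both bounds."""
    return [t for t in noncoding if min_len <= t.length <= max_len]


def orf_table_rows(orfs: Iterable[OrfResult]) -> list[dict]:
    """ORF report rows with 1-based inclusive output coordinates."""
    return [
        {
            "transcript_id": o.transcript_id,
            "strand": o.strand,
            "frame": o.frame,
            "start": o.start + 1,
            "end": o.end,
            "aa_length": o.aa_length,
            "protein": o.protein,
        }
        for o in orfs
    ]
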