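"""Greedy identity/coverage clustering across source transcriptomes.

The clustering mirrors CD-HIT's incremental algorithm: sequences are
processed longest-first and each joins the first existing cluster whose
*representative* it matches at >=98% identity over >=80% of the shorter
sequence, else it founds a new cluster. A shared-k-mer prefilter (analogous
to CD-HIT's short-word filter) skips alignments that provably cannot reach
the identity/coverage thresholds.

Consensus selection keeps clusters detected in the midgut+salivary-gland
set (the most stringently assembled source) and in at least one of the
other two transcriptomes, and reports the longest member as the consensus
sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner

from .seqio import TranscriptRecord

MGSG = "MG_SG"
OTHER_SOURCES = ("SG", "WB")


@dataclass
class Cluster:
    representative: str
    members: list[tuple[str, str]] = field(default_factory=list)  # (id, source)
    retained: bool = False


def _glocal_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    # Free end gaps on the target (the longer sequence): global-local.
    # "Deletions" are alignment columns where the target has a residue and
    # the query does not, i.e. unaligned target overhangs.
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """Identity and coverage of the shorter sequence against the longer.

    The shorter sequence is aligned end-to-end against the longer with free
    end gaps on the longer (match +1, mismatch -1, gap -2). Identity is
    matches over the alignment columns spanned by the shorter sequence;
    coverage is the fraction of the shorter sequence aligned to residues of
    the longer.
    """
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    aligner = _glocal_aligner()
    alignment = aligner.align(longer, shorter)[0]
    blocks = alignment.aligned  # ((t_start, t_end), ...), ((q_start, q_end), ...)
    t_blocks, q_blocks = blocks
    if len(t_blocks) == 0:
        return 0.0, 0.0
    matches = 0
    aligned_len = 0
    span_columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        seg_t = longer[ts:te]
        seg_q = shorter[qs:qe]
        matches += sum(x == y for x, y in zip(seg_t, seg_q))
        aligned_len += te - ts
        span_columns += te - ts
        if prev_t is not None:
            span_columns += max(ts - prev_t, qs - prev_q)
        prev_t, prev_q = te, qe
    # Shorter-sequence residues hanging off the aligned blocks (opposite end
    # gaps of the longer would not occur; opposite internal gaps already
    # counted via the inter-block jumps above). Leading/trailing shorter
    # residues aligned to longer end-gaps count toward its span.
    lead = q_blocks[0][0]
    trail = len(shorter) - q_blocks[-1][1]
    span_columns += lead + trail
    identity = matches / span_columns if span_columns else 0.0
    coverage = aligned_len / len(shorter)
    return identity, coverage


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _prefilter_threshold(ls: int, id_thr: float, cov_thr: float, k: int) -> int:
    """A deliberately slack lower bound on shared k-mer positions for any
    pair meeting (id_thr, cov_thr); pairs below it can be skipped safely."""
    intact = id_thr * cov_thr * ls - k * (2.0 * (1.0 - id_thr) * ls + 1.0) - (k - 1)
    return max(1, math.floor(intact / 2.0))


def greedy_cluster(
    sequences: Iterable[TranscriptRecord],
    id_thr: float = 0.98,
    cov_thr: float = 0.80,
    prefilter_k: int = 8,
    use_prefilter: bool = True,
) -> list[Cluster]:
    """CD-HIT-style greedy incremental clustering.

    Sequences are sorted by length descending (ties by id ascending); each
    joins the first cluster whose representative satisfies both thresholds,
    else founds a new cluster. Membership is checked against representatives
    only, matching the cited tool's semantics.
    """
    records = sorted(sequences, key=lambda r: (-r.length, r.id))
    clusters: list[Cluster] = []
    reps: list[TranscriptRecord] = []
    rep_kmers: list[set[str]] = []
    for rec in records:
        placed = False
        if use_prefilter:
            need = _prefilter_threshold(rec.length, id_thr, cov_thr, prefilter_k)
        for ci, rep in enumerate(reps):
            if use_prefilter:
                km = rep_kmers[ci]
                shared = sum(
                    1
                    for i in range(rec.length - prefilter_k + 1)
                    if rec.sequence[i : i + prefilter_k] in km
                )
                if shared < need:
                    continue
            ident, cov = pairwise_identity(rec.sequence, rep.sequence)
            if ident >= id_thr and cov >= cov_thr:
                clusters[ci].members.append((rec.id, rec.source))
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rec.id, [(rec.id, rec.source)]))
            reps.append(rec)
            rep_kmers.append(_kmer_set(rec.sequence, prefilter_k))
    return clusters


def select_consensus(
    clusters: Sequence[Cluster],
    sequences_by_id: dict[str, TranscriptRecord],
    mgsg_source: str = MGSG,
    other_sources: Sequence[str] = OTHER_SOURCES,
    require_mgsg_representative: bool = False,
) -> list[TranscriptRecord]:
    """Mark retained clusters and return their consensus sequences.

    A cluster is retained when its members include at least one sequence
    from the MG-SG source and at least one from the salivary-gland-only or
    whole-body sources. The consensus is the longest member (ties broken by
    id ascending); with ``require_mgsg_representative`` the longest MG-SG
    member is taken instead.
    """
    consensus: list[TranscriptRecord] = []
    others = set(other_sources)
    for cluster in clusters:
        sources = {src for _, src in cluster.members}
        cluster.retained = mgsg_source in sources and bool(sources & others)
        if not cluster.retained:
            continue
        pool = cluster.members
        if require_mgsg_representative:
            pool = [m for m in pool if m[1] == mgsg_source]
        best = min(pool, key=lambda m: (-sequences_by_id[m[0]].length, m[0]))
        consensus.append(sequences_by_id[best[0]])
    return consensus


def cluster_table_rows(clusters: Sequence[Cluster]) -> list[dict]:
    rows = []
    for ci, cluster in enumerate(clusters):
        for member_id, source in cluster.members:
            rows.append(
                {
                    "cluster_id": ci,
                    "representative_id": cluster.representative,
                    "member_id": member_id,
                    "source": source,
                    "retained": int(cluster.retained),
                }
            )
    return rows
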