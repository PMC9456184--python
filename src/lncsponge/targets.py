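"""miRNA target-site prediction on lncRNAs.

Prediction runs in two stages whose agreement defines a consensus site:

1. *Seed stage*: exact complementarity to the miRNA seed (positions 2-7,
   numbered from the 5' end) located on the lncRNA sense strand, classified
   upward into the canonical site taxonomy (6mer, 7mer-A1, 7mer-m8, 8mer).
2. *Hybridization stage*: a local alignment score of the full miRNA against
   the target window (Watson-Crick pair +5, G:U wobble +2, mismatch -3,
   gap open -8/extend -2, seed positions 2-8 double weighted); a site is
   kept when the score reaches ``min_hybrid_score``.

The default ``min_hybrid_score`` of 70 equals the guaranteed score of a
perfectly paired 7mer-m8 seed, so every well-formed >=7mer-m8 site passes
while 7mer-A1 sites additionally need productive 3' pairing.

The shuffled-sequence null repeats the identical prediction on randomized
lncRNAs and is the reference distribution for sponge scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import MirnaRecord, TranscriptRecord, shuffle_sequence

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}
SITE_LENGTH = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}

_RNA_COMPLEMENT_DNA = str.maketrans("ACGUN", "TGCAN")  # miRNA base -> target base


@dataclass(frozen=True)
class TargetSite:
    lncrna_id: str
    mirna_id: str
    start: int  # 0-based 5' end of the site on the lncRNA
    site_type: str
    hybrid_score: float = 0.0
    passed_consensus: bool = False

    @property
    def length(self) -> int:
        return SITE_LENGTH[self.site_type]


@dataclass(frozen=True)
class TargetParams:
    """Consensus thresholds for target prediction."""

    min_site_type: str = "7mer-A1"  # 6mers never reach consensus
    min_hybrid_score: float = 70.0
    window_3p: int = 30  # nt of target context 3'-ward of the seed site


def find_seed_sites(mirna: MirnaRecord, lncrna: TranscriptRecord) -> list[TargetSite]:
    """All seed-complementary sites of a miRNA on a lncRNA (sense strand).

    A 6mer is an exact match to the reverse complement of miRNA positions
    2-7; extension through position 8 gives 7mer-m8, an ``A`` in the target
    opposite miRNA position 1 gives 7mer-A1, and both give an 8mer. Every
    match start yields exactly one site of the highest attainable type;
    overlapping sites at distinct starts are all reported.
    """
    m = mirna.mature_sequence
    if len(m) < 8:
        raise ValueError(f"miRNA {mirna.id!r} shorter than 8 nt")
    seq = lncrna.sequence
    # Target-strand (5'->3') reverse complement of the seed: the base
    # pairing miRNA position 7 comes first, position 2 last.
    match6 = m[1:7].translate(_RNA_COMPLEMENT_DNA)[::-1]
    m8_target = m[7].translate(_RNA_COMPLEMENT_DNA)  # base pairing position 8
    sites: list[TargetSite] = []
    i = seq.find(match6)
    while i != -1:
        has_m8 = i >= 1 and seq[i - 1] == m8_target
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            site_type, start = "8mer", i - 1
        elif has_m8:
            site_type, start = "7mer-m8", i - 1
        elif has_a1:
            site_type, start = "7mer-A1", i
        else:
            site_type, start = "6mer", i
        sites.append(TargetSite(lncrna.id, mirna.id, start, site_type))
        i = seq.find(match6, i + 1)
    return sites


def _make_pair_table() -> dict[tuple[str, str], float]:
    table = {}
    for mb in "ACGUN":
        for tb in "ACGTN":
            if mb != "N" and tb == mb.translate(_RNA_COMPLEMENT_DNA):
                score = 5.0
            elif (mb == "G" and tb == "T") or (mb == "U" and tb == "G"):
                score = 2.0  # G:U wobble
            else:
                score = -3.0  # N never pairs
            table[(mb, tb)] = score
    return table


_PAIR_TABLE = _make_pair_table()


def _pair_score(mirna_base: str, target_base: str) -> float:
    return _PAIR_TABLE[(mirna_base, target_base)]


def hybrid_score(mirna_sequence: str, lncrna_window: str) -> float:
    """Best local-alignment hybridization score of a miRNA in a target window.

    The miRNA is aligned antiparallel (3'->5' against the window 5'->3');
    pair scores are doubled for miRNA seed positions 2-8. Gaps cost 8 to
    open and 2 to extend (affine, Gotoh recursion). Scores below zero are
    reported as 0.
    """
    if not lncrna_window:
        return 0.0
    lm = len(mirna_sequence)
    lw = len(lncrna_window)
    rev = mirna_sequence[::-1]
    # Row i pairs miRNA position lm - i + 1 (antiparallel orientation);
    # substitution scores for the whole row are precomputed.
    neg = -1e18
    h_prev = [0.0] * (lw + 1)
    f_prev = [neg] * (lw + 1)
    best = 0.0
    for i in range(1, lm + 1):
        mb = rev[i - 1]
        w = 2.0 if 2 <= (lm - i + 1) <= 8 else 1.0
        row_sub = [w * _pair_score(mb, c) for c in lncrna_window]
        h_cur = [0.0] * (lw + 1)
        f_cur = [neg] * (lw + 1)
        e = neg
        for j in range(1, lw + 1):
            e = max(h_cur[j - 1] - 8.0, e - 2.0)
            f_cur[j] = max(h_prev[j] - 8.0, f_prev[j] - 2.0)
            diag = h_prev[j - 1] + row_sub[j - 1]
            v = diag
            if e > v:
                v = e
            if f_cur[j] > v:
                v = f_cur[j]
            if v < 0.0:
                v = 0.0
            h_cur[j] = v
            if v > best:
                best = v
        h_prev, f_prev = h_cur, f_cur
    return float(best)


def score_site(site: TargetSite, mirna: MirnaRecord, lncrna: TranscriptRecord,
               params: TargetParams = TargetParams()) -> TargetSite:
    """Attach the hybridization score of a seed site's target window."""
    window = lncrna.sequence[site.start : site.start + site.length + params.window_3p]
    return replace(site, hybrid_score=hybrid_score(mirna.mature_sequence, window))


def predict_targets(
    mirnas: Sequence[MirnaRecord],
    lncrnas: Sequence[TranscriptRecord],
    params: TargetParams = TargetParams(),
) -> tuple[list[TargetSite], pd.DataFrame]:
    """Seed + hybridization consensus target prediction.

    Returns all seed-stage sites (with hybridization scores and consensus
    flags) and the consensus-count matrix (miRNAs x lncRNAs).
    """
    if not mirnas or not lncrnas:
        warnings.warn("empty miRNA or lncRNA set: no targets predicted")
        return [], pd.DataFrame(
            0,
            index=[m.id for m in mirnas],
            columns=[l.id for l in lncrnas],
            dtype=np.int64,
        )
    min_rank = SITE_RANK[params.min_site_type]
    sites: list[TargetSite] = []
    counts = pd.DataFrame(
        0,
        index=[m.id for m in mirnas],
        columns=[l.id for l in lncrnas],
        dtype=np.int64,
    )
    for lnc in lncrnas:
        for mir in mirnas:
            for site in find_seed_sites(mir, lnc):
                site = score_site(site, mir, lnc, params)
                consensus = (
                    SITE_RANK[site.site_type] >= min_rank
                    and site.hybrid_score >= params.min_hybrid_score
                )
                site = replace(site, passed_consensus=consensus)
                sites.append(site)
                if consensus:
                    counts.loc[mir.id, lnc.id] += 1
    return sites, counts


def build_null(
    lncrnas: Sequence[TranscriptRecord],
    mirnas: Sequence[MirnaRecord],
    n_replicates: int,
    seed: int,
    params: TargetParams = TargetParams(),
    mode: str = "mono",
) -> list[pd.DataFrame]:
    """Consensus-count matrices for shuffled copies of every lncRNA.

    Each replicate shuffles each lncRNA with a replicate- and
    sequence-indexed seed and reruns prediction with identical parameters.
    """
    if n_replicates < 1:
        raise ValueError("need at least one null replicate")
    nulls = []
    for rep in range(n_replicates):
        shuffled = [
            TranscriptRecord(
                l.id,
                shuffle_sequence(l.sequence, (seed * 1000003 + rep) * 131 + idx, mode),
                l.source,
            )
            for idx, l in enumerate(lncrnas)
        ]
        _, counts = predict_targets(mirnas, shuffled, params)
        nulls.append(counts)
    return nulls


def sites_table_rows(sites: Sequence[TargetSite]) -> list[dict]:
    """Site report rows (1-based start in output)."""
    return [
        {
            "lncrna_id": s.lncrna_id,
            "mirna_id": s.mirna_id,
            "start": s.start + 1,
            "site_type": s.site_type,
            "hybrid_score": s.hybrid_score,
            "consensus": int(s.passed_consensus),
        }
        for s in sites
    ]
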