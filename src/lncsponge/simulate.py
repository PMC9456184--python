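"""Synthetic data generator with known ground truth.

The generator emulates the statistical structure of the study design the
pipeline is built for: three overlapping assembled transcript sets (a
midgut+salivary-gland set, a salivary-gland-only set, and a whole-body
set) sharing clusters of near-identical contigs; coding clusters carrying
a planted ORF whose translation seeds the reference protein set;
negative-binomial expected counts over a fed/unfed design with planted
fold changes and variable library sizes; and lncRNAs carrying planted
miRNA seed-site clusters acting as sponge ground truth.

Background sequence is i.i.d. uniform over {A,C,G,T} - the simplest null
compatible with seed-site statistics. All outputs are byte-reproducible
from ``config.seed``; each operation derives its own RNG stream from the
seed plus a fixed per-operation offset so stages can be rerun
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import find_orfs
from .seqio import MirnaRecord, TranscriptRecord

SOURCES = ("MG_SG", "SG", "WB")
_OFFSET_TRANSCRIPTOMES = 1
_OFFSET_COUNTS = 2
_OFFSET_PLANT = 3
_OFFSET_MIRNAS = 4

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_RNA_COMPLEMENT_DNA = str.maketrans("ACGU", "TGCA")


@dataclass(frozen=True)
class SpongePlanEntry:
    """Planted sponge structure: ``n_sites`` seed sites for each listed
    miRNA written into one noncoding cluster's sequence."""

    lnc_index: int  # index into the noncoding clusters, in cluster order
    mirna_indices: tuple[int, ...]
    n_sites: int
    site_type: str = "8mer"
    length: int | None = None  # overrides the drawn cluster length

    def __post_init__(self):
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.site_type not in ("8mer", "7mer-m8"):
            raise ValueError(f"unsupported planted site type {self.site_type!r}")


def default_sponge_plan() -> tuple[SpongePlanEntry, ...]:
    """The default planted sponge structure.

    One long lncRNA with many sites for a single miRNA (the max-count
    winner), one short dense lncRNA (the density winner), and three
    disjoint groups of four lncRNAs each co-targeted by a triple of miRNAs
    (the itemset groups).
    """
    plan = [
        SpongePlanEntry(0, (0,), 10, length=1200),
        SpongePlanEntry(1, (1,), 8, length=400),
    ]
    for g, mirnas in enumerate([(2, 3, 4), (5, 6, 7), (8, 9, 10)]):
        for j in range(4):
            plan.append(SpongePlanEntry(2 + g * 4 + j, mirnas, 2, length=1000))
    return tuple(plan)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_clusters: int = 60
    p_coding: float = 0.6
    source_presence: tuple[float, float, float] = (0.9, 0.7, 0.6)
    length_range: tuple[int, int] = (300, 1500)
    mutation_rate: float = 0.005
    n_samples_per_group: int = 6
    dispersion: float = 0.15
    de_fraction: float = 0.25
    de_log2fc: float = 2.0
    n_mirnas: int = 20
    mirna_length: int = 22
    sponge_plan: tuple[SpongePlanEntry, ...] = field(default_factory=tuple)
    lncrna_share: float = 0.3  # target share of total expression for lncRNAs
    library_factor_range: tuple[float, float] = (0.5, 2.0)
    tissues: tuple[str, ...] = ("midgut", "salivary_gland")
    max_orf_retries: int = 500

    def __post_init__(self):
        for p in (self.p_coding, self.mutation_rate, self.de_fraction,
                  self.lncrna_share, *self.source_presence):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        lo, hi = self.length_range
        if not (100 <= lo <= hi <= 5000):
            raise ValueError("length_range must lie within [100, 5000]")
        if self.n_clusters < 0 or self.n_mirnas < 0:
            raise ValueError("counts must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def default_config(**overrides) -> SimulationConfig:
    """Default study conditions, including the planted sponge structure."""
    if "sponge_plan" not in overrides:
        overrides["sponge_plan"] = default_sponge_plan()
    return SimulationConfig(**overrides)


@dataclass
class GroundTruth:
    class_by_transcript: dict[str, str] = field(default_factory=dict)
    cluster_by_transcript: dict[str, int] = field(default_factory=dict)
    de_table: pd.DataFrame | None = None
    planted_sites: list[tuple[str, str, int, str]] = field(default_factory=list)
    reference_proteins: list[str] = field(default_factory=list)
    eligible_clusters: set[int] = field(default_factory=set)
    sponge_clusters: dict[int, tuple[str, ...]] = field(default_factory=dict)
    cluster_class: dict[int, str] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def simulate_mirnas(config: SimulationConfig) -> list[MirnaRecord]:
    """Synthetic mature miRNAs: position 1 is U (the dominant 5' base of
    real mature miRNAs), the remainder uniform over {A,C,G,U}."""
    rng = np.random.default_rng([config.seed, _OFFSET_MIRNAS])
    bases = np.frombuffer(b"ACGU", dtype="S1")
    out = []
    for i in range(config.n_mirnas):
        tail = rng.choice(bases, size=config.mirna_length - 1).tobytes().decode()
        out.append(MirnaRecord(f"syn-mir-{i:03d}", "U" + tail))
    return out


def _planted_site_string(mirna_seq: str, site_type: str) -> str:
    """Target-strand sequence of an exact seed site (5'->3')."""
    seed_rc = mirna_seq[1:8].translate(_RNA_COMPLEMENT_DNA)[::-1]  # pairs pos 2-8
    if site_type == "8mer":
        return seed_rc + "A"  # A opposite miRNA position 1
    return seed_rc  # 7mer-m8


def _place_blocks(
    rng: np.random.Generator, length: int, block_len: int, n_blocks: int
) -> list[int]:
    """Non-overlapping uniformly drawn start positions for equal blocks."""
    free = length - n_blocks * block_len
    if free < 0:
        raise ValueError("sequence too short")
    u = np.sort(rng.integers(0, free + 1, size=n_blocks))
    return [int(u[i] + i * block_len) for i in range(n_blocks)]


def plant_sponge_sites(
    lncrnas: Sequence[TranscriptRecord],
    mirnas: Sequence[MirnaRecord],
    sponge_plan: Sequence[SpongePlanEntry],
    seed: int,
) -> tuple[list[TranscriptRecord], list[tuple[str, str, int, str]]]:
    """Write exact seed complements into lncRNA sequences.

    For each plan entry, ``n_sites`` exact reverse complements of the
    miRNA seed (positions 2-8, plus an ``A`` opposite position 1 for 8mer
    sites) are placed at non-overlapping uniformly drawn positions.
    Returns the modified records and 0-based planted coordinates.
    """
    rng = np.random.default_rng([seed, _OFFSET_PLANT])
    seqs = [l.sequence for l in lncrnas]
    planted: list[tuple[str, str, int, str]] = []
    for entry in sponge_plan:
        lnc = lncrnas[entry.lnc_index]
        mirna_ids = [mirnas[i] for i in entry.mirna_indices]
        site_strs = [_planted_site_string(m.mature_sequence, entry.site_type)
                     for m in mirna_ids]
        site_len = max((len(s) for s in site_strs), default=0)
        n_total = entry.n_sites * len(mirna_ids)
        if n_total == 0:
            continue
        seq = seqs[entry.lnc_index]
        try:
            starts = _place_blocks(rng, len(seq), site_len, n_total)
        except ValueError:
            raise ValueError(
                f"lncRNA {lnc.id!r} ({len(seq)} nt) too short for "
                f"{n_total} planted sites of {site_len} nt"
            ) from None
        chars = list(seq)
        for k, start in enumerate(starts):
            mir = mirna_ids[k % len(mirna_ids)]
            site = site_strs[k % len(mirna_ids)]
            chars[start : start + len(site)] = site
            planted.append((lnc.id, mir.id, start, entry.site_type))
        seqs[entry.lnc_index] = "".join(chars)
    out = [replace(l, sequence=s) for l, s in zip(lncrnas, seqs)]
    return out, planted


def _embed_orf(
    rng: np.random.Generator, seq: str, min_aa: int = 55, max_aa: int = 110
) -> tuple[str, str, tuple[int, int]]:
    """Write an ATG..stop ORF into frame 0 of the forward strand; returns
    the new sequence, the translation, and the ORF window."""
    max_fit = (len(seq) - 6) // 3 - 1
    hi = min(max_aa, max_fit)
    aa_len = int(rng.integers(min_aa, hi + 1))
    codons = ["ATG"] + [
        _SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))]
        for _ in range(aa_len - 1)
    ] + [("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]]
    orf = "".join(codons)
    max_start = (len(seq) - len(orf)) // 3
    start = 3 * int(rng.integers(0, max_start + 1))
    new_seq = seq[:start] + orf + seq[start + len(orf):]
    protein = _translate(orf[:-3])
    return new_seq, protein, (start, start + len(orf))


_CODON_TABLE = {}


def _translate(cds: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for c in _SENSE_CODONS:
            _CODON_TABLE[c] = str(Seq(c).translate())
    return "".join(_CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, mask: np.ndarray | None
) -> str:
    """Substitute exactly round(rate * n_mutable) positions.

    The count is deterministic (positions random) so the pairwise
    divergence between same-cluster copies is bounded at 2*rate by
    construction and planted cluster identity is guaranteed rather than
    merely expected."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    free = np.arange(len(seq)) if mask is None else np.flatnonzero(~mask)
    k = int(round(rate * len(free)))
    if k == 0:
        return seq
    idx = rng.choice(free, size=k, replace=False)
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(0, len(choices)))]
    return arr.tobytes().decode()


def simulate_transcriptomes(
    config: SimulationConfig,
) -> tuple[dict[str, list[TranscriptRecord]], GroundTruth]:
    """Generate the three labelled transcript sets with ground truth.

    Each cluster emits a near-identical copy (substitution rate
    ``mutation_rate``) into every source it is present in. Coding clusters
    carry a planted forward-frame ORF whose translation joins the
    reference protein set; noncoding clusters are rejection-sampled until
    they contain no ORF longer than 50 aa in any frame. Planted ORF and
    sponge-site windows are masked from mutation so every copy of a
    cluster provably retains its class and its planted sites.
    """
    rng = np.random.default_rng([config.seed, _OFFSET_TRANSCRIPTOMES])
    mirnas = simulate_mirnas(config)
    truth = GroundTruth()
    sets: dict[str, list[TranscriptRecord]] = {src: [] for src in SOURCES}
    if config.n_clusters == 0:
        return sets, truth

    coding_flags = rng.random(config.n_clusters) < config.p_coding
    need = 1 + max((e.lnc_index for e in config.sponge_plan), default=-1)
    if need > config.n_clusters:
        raise ValueError(
            f"sponge plan needs {need} noncoding clusters but only "
            f"{config.n_clusters} clusters are simulated"
        )
    # Guarantee the plan fits: flip trailing coding clusters to noncoding
    # if the Bernoulli draw left too few (a rare low-tail event).
    for i in range(config.n_clusters - 1, -1, -1):
        if int((~coding_flags).sum()) >= need:
            break
        coding_flags[i] = False
    noncoding_order = [i for i in range(config.n_clusters) if not coding_flags[i]]
    plan_by_cluster: dict[int, list[SpongePlanEntry]] = {}
    for entry in config.sponge_plan:
        plan_by_cluster.setdefault(noncoding_order[entry.lnc_index], []).append(entry)

    lo, hi = config.length_range
    for ci in range(config.n_clusters):
        coding = bool(coding_flags[ci])
        entries = plan_by_cluster.get(ci, [])
        length = int(rng.integers(lo, hi + 1))
        for entry in entries:
            if entry.length is not None:
                length = entry.length
        mask = np.zeros(length, dtype=bool)
        base = None
        for attempt in range(config.max_orf_retries):
            seq = _random_seq(rng, length)
            if coding:
                seq, protein, (a, b) = _embed_orf(rng, seq)
                mask[:] = False
                mask[a:b] = True
                base = seq
                break
            seq, site_records = _plant_cluster_sites(rng, seq, entries, mirnas, mask)
            if not find_orfs(("x", seq), min_aa=50):
                base = seq
                break
        else:
            raise RuntimeError(
                f"cluster {ci}: could not generate an ORF-free sequence in "
                f"{config.max_orf_retries} attempts"
            )
        if coding:
            truth.reference_proteins.append(protein)
            site_records = []
        truth.cluster_class[ci] = "coding" if coding else "noncoding"

        presence = _draw_presence(rng, config, bool(entries))
        truth.eligible_clusters -= {ci}
        if presence[0] and (presence[1] or presence[2]):
            truth.eligible_clusters.add(ci)
        if entries:
            truth.sponge_clusters[ci] = tuple(
                mirnas[i].id for e in entries for i in e.mirna_indices
            )
        for s_idx, src in enumerate(SOURCES):
            if not presence[s_idx]:
                continue
            copy_seq = _mutate(rng, base, config.mutation_rate, mask)
            tid = f"C{ci:04d}.{src}"
            sets[src].append(TranscriptRecord(tid, copy_seq, src))
            truth.class_by_transcript[tid] = "coding" if coding else "noncoding"
            truth.cluster_by_transcript[tid] = ci
            for _, mir_id, start, site_type in site_records:
                truth.planted_sites.append((tid, mir_id, start, site_type))
    return sets, truth


def _plant_cluster_sites(
    rng: np.random.Generator,
    seq: str,
    entries: Sequence[SpongePlanEntry],
    mirnas: Sequence[MirnaRecord],
    mask: np.ndarray,
) -> tuple[str, list[tuple[str, str, int, str]]]:
    mask[:] = False
    records: list[tuple[str, str, int, str]] = []
    if not entries:
        return seq, records
    blocks: list[tuple[str, str, str]] = []  # (mirna id, site string, type)
    for entry in entries:
        for i in entry.mirna_indices:
            site = _planted_site_string(mirnas[i].mature_sequence, entry.site_type)
            blocks.extend((mirnas[i].id, site, entry.site_type)
                          for _ in range(entry.n_sites))
    if not blocks:
        return seq, records
    site_len = max(len(s) for _, s, _ in blocks)
    try:
        starts = _place_blocks(rng, len(seq), site_len, len(blocks))
    except ValueError:
        raise ValueError(
            f"sequence of {len(seq)} nt too short for {len(blocks)} planted sites"
        ) from None
    chars = list(seq)
    order = rng.permutation(len(blocks))
    for start, bi in zip(starts, order):
        mir_id, site, site_type = blocks[int(bi)]
        chars[start : start + len(site)] = site
        mask[start : start + len(site)] = True
        records.append((None, mir_id, start, site_type))
    return "".join(chars), records


def _draw_presence(
    rng: np.random.Generator, config: SimulationConfig, force_eligible: bool
) -> tuple[bool, bool, bool]:
    if force_eligible:
        # Sponge clusters must survive consensus selection.
        return (True, True, bool(rng.random() < config.source_presence[2]))
    for _ in range(1000):
        draw = tuple(rng.random(3) < np.asarray(config.source_presence))
        if any(draw):
            return draw
    return (True, False, False)  # pragma: no cover - presence all ~0


def simulate_counts(
    transcripts: Sequence[TranscriptRecord],
    config: SimulationConfig,
    classes: Mapping[str, str] | None = None,
    force_up_fed: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """NB-distributed expected counts over a (tissue x condition) design.

    Base means are log-uniform; lncRNAs are scaled so their expected share
    of total expression matches ``config.lncrna_share``. A ``de_fraction``
    of transcripts receive a planted fed/unfed fold change of
    ``de_log2fc`` with random sign (ids in ``force_up_fed`` are always
    planted up in fed); per-sample library-size factors are log-uniform in
    [0.5, 2]. Returns (counts, sample table, DE truth table).
    """
    if config.n_samples_per_group < 2:
        raise ValueError("need at least 2 samples per (tissue, condition) group")
    rng = np.random.default_rng([config.seed, _OFFSET_COUNTS])
    ids = [t.id for t in transcripts]
    n = len(ids)
    base = 2.0 ** rng.uniform(5.0, 9.0, size=n)
    if classes is not None and 0 < config.lncrna_share < 1:
        is_lnc = np.array([classes.get(i) in ("noncoding", "lncRNA") for i in ids])
        n_lnc, n_cod = int(is_lnc.sum()), int((~is_lnc).sum())
        if n_lnc and n_cod:
            share = config.lncrna_share
            scale = (share / (1 - share)) * (n_cod / n_lnc)
            base[is_lnc] *= scale
    forced = set(force_up_fed)
    is_de = rng.random(n) < config.de_fraction
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    lfc = np.where(is_de, sign * config.de_log2fc, 0.0)
    for k, tid in enumerate(ids):
        if tid in forced:
            is_de[k] = True
            lfc[k] = config.de_log2fc
    sample_rows = []
    columns = {}
    for tissue in config.tissues:
        for condition in ("unfed", "fed"):
            for r in range(config.n_samples_per_group):
                sid = f"{tissue}_{condition}_{r + 1}"
                flo, fhi = config.library_factor_range
                lib_factor = float(np.exp(rng.uniform(np.log(flo), np.log(fhi))))
                mean = base * (2.0 ** lfc if condition == "fed" else 1.0)
                mean = mean * lib_factor
                if config.dispersion > 0:
                    r_nb = 1.0 / config.dispersion
                    p_nb = r_nb / (r_nb + mean)
                    counts = rng.negative_binomial(r_nb, p_nb)
                else:
                    counts = rng.poisson(mean)
                columns[sid] = counts
                sample_rows.append(
                    {"sample_id": sid, "tissue": tissue, "condition": condition,
                     "timepoint": pd.NA, "study": "synthetic"}
                )
    counts_df = pd.DataFrame(columns, index=ids, dtype=float)
    sample_table = pd.DataFrame(sample_rows).set_index("sample_id")
    de_table = pd.DataFrame(
        {"true_log2fc": lfc, "is_de": is_de}, index=ids
    )
    return counts_df, sample_table, de_table


def make_filter_fixture(
    n_pass: int,
    n_fail: int,
    sample_table: pd.DataFrame,
    seed: int,
    min_fpkm: float = 5.0,
) -> tuple[pd.DataFrame, list[str]]:
    """An FPKM matrix with planted expression-filter passers and failers.

    Passers reach ``min_fpkm`` in every sample of one condition group;
    failers fall below it in at least one sample of *every* group.
    """
    from .expression import expression_groups

    rng = np.random.default_rng([seed, 7])
    groups = list(expression_groups(sample_table).values())
    samples = list(sample_table.index)
    rows, ids, pass_ids = [], [], []
    for k in range(n_pass):
        tid = f"PASS{k:04d}"
        vals = pd.Series(rng.uniform(0.0, min_fpkm * 0.98, size=len(samples)),
                         index=samples)
        g = groups[int(rng.integers(0, len(groups)))]
        vals[g] = rng.uniform(min_fpkm, min_fpkm * 10, size=len(g))
        ids.append(tid)
        pass_ids.append(tid)
        rows.append(vals)
    for k in range(n_fail):
        tid = f"FAIL{k:04d}"
        vals = pd.Series(rng.uniform(min_fpkm, min_fpkm * 10, size=len(samples)),
                         index=samples)
        for g in groups:
            low = g[int(rng.integers(0, len(g)))]
            vals[low] = rng.uniform(0.0, min_fpkm * 0.98)
        ids.append(tid)
        rows.append(vals)
    fpkm = pd.DataFrame(rows, index=ids)
    return fpkm, pass_ids
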