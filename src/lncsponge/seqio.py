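"""FASTA input/output and shuffled-sequence null generation.

Transcripts are handled as DNA (``U`` normalized to ``T`` on input); mature
miRNAs are handled as RNA. The shuffled-sequence generator provides the
negative-control sequences used downstream by the target-prediction null:
a plain mononucleotide permutation (the default, matching EMBOSS
``shuffleseq`` behaviour) and a dinucleotide-preserving shuffle built from an
Euler path on the de Bruijn multigraph, for users who want a null that keeps
local composition intact.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT_DNA = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class TranscriptRecord:
    """An assembled contig with its source transcriptome label."""

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: invalid DNA characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MirnaRecord:
    """A mature miRNA (RNA alphabet, 5'->3')."""

    id: str
    mature_sequence: str

    def __post_init__(self) -> None:
        if not self.mature_sequence:
            raise ValueError(f"miRNA {self.id!r}: empty sequence")
        bad = set(self.mature_sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"miRNA {self.id!r}: invalid RNA characters {sorted(bad)}"
            )


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT_DNA)[::-1]


def read_fasta(path: str | Path, expected_alphabet: Literal["dna", "rna"] = "dna"):
    """Read a FASTA file into ``(id, sequence)`` tuples.

    Sequences are upper-cased. With ``expected_alphabet="dna"``, ``U`` is
    normalized to ``T`` (assembled transcripts are routinely deposited with
    either letter). Duplicate ids and empty sequences are errors.
    """
    if expected_alphabet not in ("dna", "rna"):
        raise ValueError(f"unknown alphabet {expected_alphabet!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    allowed = DNA_ALPHABET if expected_alphabet == "dna" else RNA_ALPHABET
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        seq = str(rec.seq).upper()
        if expected_alphabet == "dna":
            seq = seq.replace("U", "T")
        else:
            seq = seq.replace("T", "U")
        if not name:
            raise ValueError(f"{path}: record with empty header")
        if not seq:
            raise ValueError(f"{path}: record {name!r} has an empty sequence")
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"{path}: record {name!r} has characters {sorted(bad)} outside "
                f"the {expected_alphabet.upper()} alphabet"
            )
        if name in seen:
            raise ValueError(f"{path}: duplicate sequence id {name!r}")
        seen.add(name)
        records.append((name, seq))
    return records


def read_transcripts(path: str | Path, source: str = "") -> list[TranscriptRecord]:
    return [TranscriptRecord(i, s, source) for i, s in read_fasta(path, "dna")]


def read_mirnas(path: str | Path) -> list[MirnaRecord]:
    return [MirnaRecord(i, s) for i, s in read_fasta(path, "rna")]


def write_fasta(path: str | Path, records: Iterable, width: int = 60) -> None:
    """Write records (anything with ``id`` and a sequence attribute, or
    ``(id, seq)`` tuples) as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                name, seq = rec
            else:
                name = rec.id
                seq = getattr(rec, "sequence", None) or rec.mature_sequence
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def shuffle_sequence(
    sequence: str, seed: int, mode: Literal["mono", "di"] = "mono"
) -> str:
    """Shuffle a sequence preserving mono- or dinucleotide composition.

    ``mono`` draws a uniform random permutation of the characters.  ``di``
    performs an Altschul-Erickson dinucleotide-preserving shuffle: the
    sequence is a walk on the de Bruijn multigraph whose edges are its
    dinucleotides, and a random Euler path with the same endpoints is drawn,
    so all 16 dinucleotide counts are conserved exactly.
    """
    if not sequence:
        raise ValueError("cannot shuffle an empty sequence")
    rng = random.Random(seed)
    if mode == "mono":
        chars = list(sequence)
        rng.shuffle(chars)
        return "".join(chars)
    if mode != "di":
        raise ValueError(f"unknown shuffle mode {mode!r}")
    if len(sequence) < 3 or len(set(sequence)) == 1:
        return sequence
    return _euler_shuffle(sequence, rng)


def _euler_shuffle(sequence: str, rng: random.Random) -> str:
    # Edge multiset: successors of each vertex (= character).
    succ: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        succ.setdefault(a, []).append(b)
    first, last = sequence[0], sequence[-1]
    vertices = [v for v in succ if v != last]
    # Draw random "last exit" edges until they form an arborescence toward
    # the sink vertex; this is the Altschul-Erickson acceptance step and
    # guarantees the subsequent greedy walk is an Euler path.
    for _ in range(10000):
        last_exit = {v: rng.choice(succ[v]) for v in vertices}
        if _reaches_sink(last_exit, last):
            break
    else:  # pragma: no cover - astronomically unlikely for DNA
        raise RuntimeError("dinucleotide shuffle failed to find an Euler path")
    out_edges: dict[str, list[str]] = {}
    for v, targets in succ.items():
        targets = list(targets)
        if v in last_exit:
            targets.remove(last_exit[v])
        rng.shuffle(targets)
        if v in last_exit:
            targets.append(last_exit[v])
        out_edges[v] = targets
    walk = [first]
    pos = {v: 0 for v in out_edges}
    v = first
    for _ in range(len(sequence) - 1):
        nxt = out_edges[v][pos[v]]
        pos[v] += 1
        walk.append(nxt)
        v = nxt
    return "".join(walk)


def _reaches_sink(last_exit: dict[str, str], sink: str) -> bool:
    for start in last_exit:
        v = start
        seen = set()
        while v != sink:
            if v in seen or v not in last_exit:
                return False
            seen.add(v)
            v = last_exit[v]
    return True
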