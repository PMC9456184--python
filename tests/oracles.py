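"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is written as the most direct possible evaluation of the
definition (position-by-position scans, exhaustive enumeration, plain
step-by-step formulas) and shares no code with the package internals.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def orf_scan_oracle(seq: str, min_aa: int = 50, both_strands: bool = True):
    """Every ATG..first-in-frame-stop ORF with aa_length > min_aa, as a set
    of (strand, forward_start, forward_end, aa_length)."""
    out = set()
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", revcomp(seq)))
    n = len(seq)
    for strand, s in strands:
        for start in range(0, len(s) - 2):
            if s[start : start + 3] != "ATG":
                continue
            stop = None
            for j in range(start + 3, len(s) - 2, 3):
                if s[j : j + 3] in _STOPS:
                    stop = j
                    break
            if stop is None:
                continue
            aa = (stop - start) // 3
            if aa <= min_aa:
                continue
            end = stop + 3
            if strand == "+":
                out.add((strand, start, end, aa))
            else:
                out.add((strand, n - end, n - start, aa))
    return out


def seed_scan_oracle(mirna_rna: str, lnc_dna: str):
    """Position-by-position seed matching; returns {(start, site_type)}."""
    rna_to_dna_comp = {"A": "T", "C": "G", "G": "C", "U": "A", "N": "N"}
    # Target site read 5'->3' pairs miRNA positions high->low.
    pairs_pos = lambda p: rna_to_dna_comp[mirna_rna[p - 1]]
    out = set()
    for i in range(len(lnc_dna) - 5):
        if any(lnc_dna[i + k] != pairs_pos(7 - k) for k in range(6)):
            continue  # positions 7..2 at offsets 0..5
        m8 = i - 1 >= 0 and lnc_dna[i - 1] == pairs_pos(8)
        a1 = i + 6 < len(lnc_dna) and lnc_dna[i + 6] == "A"
        if m8 and a1:
            out.add((i - 1, "8mer"))
        elif m8:
            out.add((i - 1, "7mer-m8"))
        elif a1:
            out.add((i, "7mer-A1"))
        else:
            out.add((i, "6mer"))
    return out


def itemset_oracle(binary: np.ndarray, items: list[str], min_support: int,
                   min_size: int = 2):
    """Exhaustive enumeration of all itemsets; binary is items x transactions.
    Returns {(itemset tuple, support)}."""
    out = set()
    for size in range(min_size, len(items) + 1):
        for combo in combinations(range(len(items)), size):
            support = int(np.all(binary[list(combo)], axis=0).sum())
            if support >= min_support:
                out.add((tuple(items[i] for i in combo), support))
    return out


def tmm_oracle(counts: np.ndarray, samples: list[str]):
    """Plain step-by-step trimmed mean of M-values.

    Reference: upper quartile of library-scaled counts closest to the mean
    upper quartile. Per sample, M/A on genes positive in both, double trim
    (30% on M, 5% on A, two-sided on average ranks), precision-weighted
    mean, 2**f, then geometric-mean rescaling.
    """
    lib = counts.sum(axis=0).astype(float)
    scaled = counts / lib
    uq = np.quantile(scaled, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    def avg_rank(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    log_factors = np.zeros(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        y, r = counts[:, k].astype(float), counts[:, ref].astype(float)
        keep = (y > 0) & (r > 0)
        y, r = y[keep], r[keep]
        m = np.log2((y / lib[k]) / (r / lib[ref]))
        a = 0.5 * np.log2((y / lib[k]) * (r / lib[ref]))
        if np.max(np.abs(m)) < 1e-10:
            continue
        n = len(m)
        rm, ra = avg_rank(m), avg_rank(a)
        lo_m = np.floor(n * 0.3) + 1
        lo_a = np.floor(n * 0.05) + 1
        sel = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
        if not sel.any():
            continue
        w = (lib[k] - y) / (lib[k] * y) + (lib[ref] - r) / (lib[ref] * r)
        log_factors[k] = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return dict(zip(samples, factors))


def bh_oracle(pvals: list[float]) -> list[float]:
    """Step-up BH evaluated directly from the definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    prev = 1.0
    for rank_from_end in range(n, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * n / rank_from_end)
        adj[i] = val
        prev = val
    return adj
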