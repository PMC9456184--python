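"""Sponge-candidate scoring of lncRNAs against host miRNAs.

Three complementary rankings identify competing-endogenous-RNA ("sponge")
candidates from the consensus target-count matrix:

* the (miRNA, lncRNA) pair with the greatest number of target sites;
* the pair with the greatest target density (sites per kb of lncRNA);
* groups of miRNAs that consistently co-target sets of lncRNAs, mined with
  the Apriori frequent-itemset algorithm and assessed against the
  shuffled-sequence null via empirical p-values.

A per-miRNA normalized target ratio (feeding-regulated target load, fed
over unfed) prioritizes miRNAs for downstream pathway analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import bh_adjust


@dataclass(frozen=True)
class SpongeCandidate:
    lncrna_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    approach: str  # max_count | density | itemset
    score: float
    null_comparison: float  # real/null ratio or empirical p


@dataclass(frozen=True)
class ItemsetResult:
    items: tuple[str, ...]  # miRNA ids, sorted
    support: int
    supporting_lncrnas: tuple[str, ...]
    empirical_p: float = float("nan")
    fdr: float = float("nan")


def normalized_target_ratio(
    counts_up_fed: pd.Series,
    counts_up_unfed: pd.Series,
    pseudocount: float = 1.0,
    top_k: int = 3,
) -> pd.DataFrame:
    """Per-miRNA ratio of normalized target counts, fed over unfed.

    Each set's counts are normalized by the set's maximum (after adding a
    pseudocount so zero denominators are defined); the ratio ranks miRNAs
    whose target load shifts toward feeding-upregulated lncRNAs. Returns
    all miRNAs sorted by descending ratio with a ``top`` flag on the first
    ``top_k``.
    """
    if counts_up_fed.empty or counts_up_unfed.empty:
        raise ValueError("empty miRNA count vector")
    fed = counts_up_fed.astype(float) + pseudocount
    unfed = counts_up_unfed.reindex(counts_up_fed.index).astype(float) + pseudocount
    n_fed = fed / fed.max()
    n_unfed = unfed / unfed.max()
    ratio = (n_fed / n_unfed).sort_values(ascending=False, kind="mergesort")
    out = pd.DataFrame(
        {
            "normalized_fed": n_fed.reindex(ratio.index),
            "normalized_unfed": n_unfed.reindex(ratio.index),
            "ratio": ratio,
        }
    )
    out["rank"] = np.arange(1, len(out) + 1)
    out["top"] = out["rank"] <= top_k
    return out


def _best_pair(score_matrix: pd.DataFrame) -> tuple[str, str, float] | None:
    best = None
    for mirna in score_matrix.index:
        row = score_matrix.loc[mirna]
        for lncrna in score_matrix.columns:
            v = row[lncrna]
            if v <= 0:
                continue
            key = (-v, lncrna, mirna)
            if best is None or key < best[0]:
                best = (key, mirna, lncrna, float(v))
    if best is None:
        return None
    return best[1], best[2], best[3]


def _null_mean(null_matrices: Sequence[pd.DataFrame], mirna: str, lncrna: str) -> float:
    if not null_matrices:
        return float("nan")
    return float(np.mean([m.loc[mirna, lncrna] for m in null_matrices]))


def top_by_count(
    count_matrix: pd.DataFrame,
    null_matrices: Sequence[pd.DataFrame] = (),
    pseudocount: float = 1.0,
) -> SpongeCandidate | None:
    """The (miRNA, lncRNA) pair with the most consensus target sites.

    Ties break lexicographically on (lncRNA id, miRNA id). The null
    comparison is the real count over the shuffled-null mean count plus a
    pseudocount."""
    found = _best_pair(count_matrix.astype(float))
    if found is None:
        warnings.warn("all-zero target-count matrix: no max-count candidate")
        return None
    mirna, lncrna, score = found
    null = _null_mean(null_matrices, mirna, lncrna)
    comparison = score / (null + pseudocount) if not np.isnan(null) else float("nan")
    return SpongeCandidate((lncrna,), (mirna,), "max_count", score, comparison)


def top_by_density(
    count_matrix: pd.DataFrame,
    lengths: pd.Series,
    null_matrices: Sequence[pd.DataFrame] = (),
    pseudocount: float = 1.0,
) -> SpongeCandidate | None:
    """The pair with the most target sites per kb of lncRNA."""
    lengths = lengths.reindex(count_matrix.columns)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("positive lncRNA lengths required for density")
    density = count_matrix.astype(float) * 1000.0 / lengths
    found = _best_pair(density)
    if found is None:
        warnings.warn("all-zero target-count matrix: no density candidate")
        return None
    mirna, lncrna, score = found
    null = _null_mean(null_matrices, mirna, lncrna)
    real = float(count_matrix.loc[mirna, lncrna])
    comparison = real / (null + pseudocount) if not np.isnan(null) else float("nan")
    return SpongeCandidate((lncrna,), (mirna,), "density", score, comparison)


def default_min_support(n_lncrnas: int) -> int:
    """Default Apriori minimum support: max(3, 5% of lncRNA transactions)."""
    return max(3, int(np.ceil(0.05 * n_lncrnas)))


def binarize(count_matrix: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Item -> transaction mapping: miRNA -> set of lncRNAs it targets."""
    present = count_matrix >= 1
    return {
        str(mirna): frozenset(present.columns[present.loc[mirna]])
        for mirna in present.index
    }


def mine_itemsets(
    count_matrix: pd.DataFrame,
    min_support: int | None = None,
    min_size: int = 2,
) -> list[ItemsetResult]:
    """Apriori frequent-itemset mining over the binarized target matrix.

    Transactions are lncRNAs, items are miRNAs; an itemset's support is
    the number of lncRNAs targeted by *every* member. The level-wise
    search prunes by downward closure; all itemsets with at least
    ``min_size`` items and support >= ``min_support`` are returned.
    """
    if min_support is None:
        min_support = default_min_support(count_matrix.shape[1])
    if min_support < 1:
        raise ValueError("min_support must be at least 1")
    item_tx = binarize(count_matrix)
    current = {
        (item,): tx for item, tx in sorted(item_tx.items()) if len(tx) >= min_support
    }
    results: list[ItemsetResult] = []
    size = 1
    while current:
        if size >= min_size:
            for items, tx in sorted(current.items()):
                results.append(ItemsetResult(items, len(tx), tuple(sorted(tx))))
        # Candidate generation: join itemsets sharing a (k-1)-prefix, then
        # prune candidates with an infrequent subset (downward closure).
        keys = sorted(current)
        frequent = set(keys)
        nxt: dict[tuple[str, ...], frozenset[str]] = {}
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break
                cand = a + (b[-1],)
                if any(
                    cand[:j] + cand[j + 1 :] not in frequent for j in range(size + 1)
                ):
                    continue
                tx = current[a] & item_tx[b[-1]]
                if len(tx) >= min_support:
                    nxt[cand] = tx
        current = nxt
        size += 1
    results.sort(key=lambda r: (-r.support, len(r.items), r.items))
    return results


def itemset_support_in(items: Sequence[str], count_matrix: pd.DataFrame) -> int:
    present = count_matrix.loc[list(items)] >= 1
    return int(present.all(axis=0).sum())


def itemset_significance(
    itemsets: Sequence[ItemsetResult],
    null_matrices: Sequence[pd.DataFrame],
) -> list[ItemsetResult]:
    """Empirical p-values for mined itemsets against the shuffled null.

    p = (1 + #{null replicates with support >= observed}) / (1 + n), the
    standard never-zero permutation estimator, BH-adjusted across itemsets.
    """
    if not null_matrices:
        raise ValueError("at least one null matrix required")
    n = len(null_matrices)
    pvals = []
    for itemset in itemsets:
        exceed = sum(
            1
            for m in null_matrices
            if itemset_support_in(itemset.items, m) >= itemset.support
        )
        pvals.append((1 + exceed) / (1 + n))
    fdrs = bh_adjust(pvals) if itemsets else []
    return [
        ItemsetResult(r.items, r.support, r.supporting_lncrnas, p, f)
        for r, p, f in zip(itemsets, pvals, fdrs)
    ]


def select_itemset_groups(
    itemsets: Sequence[ItemsetResult],
    max_groups: int = 3,
    alpha: float = 0.05,
) -> list[ItemsetResult]:
    """Greedy selection of significant, lncRNA-disjoint co-targeting groups.

    Itemsets with empirical p <= ``alpha`` are scanned by ascending p; ties
    prefer larger itemsets then larger support (a maximal miRNA combination
    is the more informative sponge group than any of its subsets, which
    attain the same support by downward closure). A group is kept only if
    its supporting lncRNAs are disjoint from all previously kept groups.
    """
    significant = [r for r in itemsets if r.empirical_p <= alpha]
    significant.sort(
        key=lambda r: (r.empirical_p, -len(r.items), -r.support, r.items)
    )
    chosen: list[ItemsetResult] = []
    used: set[str] = set()
    for r in significant:
        if len(chosen) >= max_groups:
            break
        support_set = set(r.supporting_lncrnas)
        if support_set & used:
            continue
        chosen.append(r)
        used |= support_set
    return chosen


def select_sponge_candidates(
    count_matrix: pd.DataFrame,
    lengths: pd.Series,
    null_matrices: Sequence[pd.DataFrame],
    itemsets: Sequence[ItemsetResult],
    max_groups: int = 3,
    alpha: float = 0.05,
) -> list[SpongeCandidate]:
    """Final candidate report: max-count pair, max-density pair, and up to
    ``max_groups`` significant disjoint co-targeting groups."""
    candidates: list[SpongeCandidate] = []
    for cand in (
        top_by_count(count_matrix, null_matrices),
        top_by_density(count_matrix, lengths, null_matrices),
    ):
        if cand is not None:
            candidates.append(cand)
    for group in select_itemset_groups(itemsets, max_groups, alpha):
        candidates.append(
            SpongeCandidate(
                group.supporting_lncrnas,
                group.items,
                "itemset",
                float(group.support),
                group.empirical_p,
            )
        )
    return candidates


def candidate_log2fc_table(
    candidates: Sequence[SpongeCandidate],
    de_by_tissue: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """log2 fold-change (fed vs unfed) per candidate lncRNA and tissue,
    the content of the sponge-candidate expression heat map."""
    rows = []
    for cand in candidates:
        for lnc in cand.lncrna_ids:
            row = {"lncrna_id": lnc, "approach": cand.approach,
                   "mirnas": ",".join(cand.mirna_ids)}
            for tissue, de in de_by_tissue.items():
                row[f"log2fc_{tissue}"] = (
                    float(de.loc[lnc, "log2fc"]) if lnc in de.index else float("nan")
                )
            rows.append(row)
    return pd.DataFrame(rows)
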