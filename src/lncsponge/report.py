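"""Dataset-level summary statistics.

Pure functions over pipeline outputs: percentage of consensus transcripts
called differentially expressed, cross-study overlap of DE calls, the share
of total expression carried by lncRNAs, and length histograms.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


def de_summary(n_de: int, n_total: int) -> float:
    """Percentage of transcripts differentially expressed, one decimal
    (half-up rounding, matching how such tables are conventionally printed)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_de <= n_total:
        raise ValueError("need 0 <= n_de <= n_total")
    pct = Decimal(100 * n_de) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def overlap_analysis(set_a: Iterable[str], set_b: Iterable[str]) -> dict:
    """Venn counts and overlap percentages between two DE id sets.

    The headline overlap percentage is 100 * |A intersect B| / |A union B|
    (Jaccard); per-study percentages (intersection over each study's own
    set) are reported alongside since either denominator convention is in
    circulation.
    """
    a, b = set(set_a), set(set_b)
    inter = a & b
    union = a | b
    if not union:
        warnings.warn("both sets empty: overlap undefined, reported as 0")
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
        "n_a_only": len(a - b),
        "n_b_only": len(b - a),
        "overlap_pct": 100.0 * len(inter) / len(union) if union else 0.0,
        "overlap_pct_of_a": 100.0 * len(inter) / len(a) if a else 0.0,
        "overlap_pct_of_b": 100.0 * len(inter) / len(b) if b else 0.0,
    }


def expression_share(
    normalized_expression: pd.DataFrame,
    class_labels: pd.Series,
    sample_table: pd.DataFrame,
    target_class: str = "lncRNA",
    condition_cols: Sequence[str] = ("tissue", "condition"),
) -> tuple[pd.Series, pd.Series]:
    """Per-sample share of total expression carried by one transcript class,
    and its mean per condition group."""
    labels = class_labels.reindex(normalized_expression.index)
    totals = normalized_expression.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("samples with zero total expression")
    share = normalized_expression.loc[labels == target_class].sum(axis=0) / totals
    cols = [c for c in condition_cols if c in sample_table.columns]
    key = sample_table.loc[share.index, cols].astype(str).agg("_".join, axis=1)
    per_condition = share.groupby(key).mean()
    return share, per_condition


def length_histogram(lengths: Iterable[int], bin_width: int) -> pd.Series:
    """Counts in half-open bins [k*w, (k+1)*w); total is conserved."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        return pd.Series(dtype=np.int64)
    bins = arr // bin_width
    counts = pd.Series(bins).value_counts().sort_index()
    counts.index = [f"[{k * bin_width},{(k + 1) * bin_width})" for k in counts.index]
    return counts.astype(np.int64)
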