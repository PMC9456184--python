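"""Expression normalization and differential expression between feeding states.

Counts are RSEM-style expected counts (possibly fractional) per transcript
and sample. The module provides FPKM computation, the per-condition
expression filter (>= 5 FPKM in every sample of at least one condition/time
group), trimmed-mean-of-M-values (TMM) between-sample normalization, a
method-of-moments common negative-binomial dispersion estimator, and the
classic two-group exact NB test conditioned on per-transcript totals, with
Benjamini-Hochberg correction and fed/unfed direction calls.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import nbinom, binom, rankdata
from statsmodels.stats.multitest import multipletests

UNFED, FED = "unfed", "fed"


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM = count / (length/1000) / (library_size/1e6)."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:3]
        raise ValueError(f"missing effective lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        zero = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size in samples {zero}")
    return counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)


def expression_groups(sample_table: pd.DataFrame) -> dict[str, list[str]]:
    """Filter groups: one group of all unfed samples, plus one group per
    fed timepoint (all fed samples if no timepoint is recorded)."""
    groups: dict[str, list[str]] = {}
    unfed = sample_table.index[sample_table["condition"] == UNFED].tolist()
    if unfed:
        groups[UNFED] = unfed
    fed = sample_table[sample_table["condition"] == FED]
    if "timepoint" in fed.columns and fed["timepoint"].notna().any():
        for tp, sub in fed.groupby("timepoint", dropna=False):
            key = f"{FED}_{tp}" if pd.notna(tp) else FED
            groups[key] = sub.index.tolist()
    elif len(fed):
        groups[FED] = fed.index.tolist()
    return groups


def expression_filter(
    fpkm: pd.DataFrame, sample_table: pd.DataFrame, min_fpkm: float = 5.0
) -> list[str]:
    """Transcripts with FPKM >= ``min_fpkm`` in *every* sample of at least
    one condition/timepoint group."""
    groups = expression_groups(sample_table)
    keep = pd.Series(False, index=fpkm.index)
    for name, samples in groups.items():
        if not samples:
            warnings.warn(f"expression filter group {name!r} has no samples")
            continue
        keep |= (fpkm[samples] >= min_fpkm).all(axis=1)
    return fpkm.index[keep].tolist()


def tmm_factors(counts: pd.DataFrame, ref_sample: str | None = None) -> pd.Series:
    """Trimmed mean of M-values normalization factors (Robinson-Oshlack).

    M- and A-values versus the reference are computed on transcripts with
    positive counts in both samples, doubly trimmed (30% on M, 5% on A,
    two-sided), and averaged with precision (delta-method) weights. Factors
    are rescaled to a geometric mean of one. The reference defaults to the
    sample whose upper-quartile scaled count is closest to the mean upper
    quartile.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        zero = lib.index[lib <= 0].tolist()
        raise ValueError(f"all-zero samples: {zero}")
    if ref_sample is None:
        uq = counts.div(lib, axis=1).quantile(0.75, axis=0)
        ref_sample = (uq - uq.mean()).abs().idxmin()
    factors = {}
    for sample in counts.columns:
        factors[sample] = 2.0 ** _tmm_log_factor(
            counts[sample].to_numpy(float),
            counts[ref_sample].to_numpy(float),
            lib[sample],
            lib[ref_sample],
        )
    f = pd.Series(factors, index=counts.columns)
    return f / np.exp(np.log(f).mean())


def _tmm_log_factor(
    y: np.ndarray,
    r: np.ndarray,
    ny: float,
    nr: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    ok = (y > 0) & (r > 0)
    y, r = y[ok], r[ok]
    if y.size == 0:
        return 0.0
    py, pr = y / ny, r / nr
    m = np.log2(py / pr)
    a = 0.5 * np.log2(py * pr)
    if np.allclose(m, 0.0, atol=1e-10):
        return 0.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    v = (ny - y) / (ny * y) + (nr - r) / (nr * r)  # asymptotic var of M
    return float(np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))


def effective_library_sizes(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    lib_sizes: pd.Series | None = None,
) -> pd.Series:
    lib = counts.sum(axis=0).astype(float) if lib_sizes is None \
        else lib_sizes.reindex(counts.columns).astype(float)
    if (lib <= 0).any():
        raise ValueError(
            f"non-positive library sizes: {lib.index[lib <= 0].tolist()}"
        )
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    return lib * factors.reindex(counts.columns)


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: Sequence[str] | pd.Series,
    factors: pd.Series | None = None,
) -> float:
    """Method-of-moments common NB dispersion.

    Counts are scaled to a common effective library size; per transcript the
    within-group variance is pooled and phi_t = max(0, (s^2 - m) / m^2);
    the estimate is the median of phi_t over transcripts with mean > 1.
    """
    groups = pd.Series(np.asarray(groups), index=counts.columns)
    sizes = groups.value_counts()
    if not (sizes >= 2).any():
        raise ValueError(
            "no group has replicates; supply a dispersion value explicitly"
        )
    eff = effective_library_sizes(counts, factors)
    common = float(np.exp(np.log(eff).mean()))
    scaled = counts * (common / eff)
    means, ss, dfs = [], [], []
    for g in sizes.index:
        sub = scaled.loc[:, groups[groups == g].index]
        if sub.shape[1] < 2:
            continue
        means.append(sub.mean(axis=1))
        ss.append(sub.var(axis=1, ddof=1) * (sub.shape[1] - 1))
        dfs.append(sub.shape[1] - 1)
    m = pd.concat(means, axis=1).mean(axis=1)
    s2 = sum(ss) / sum(dfs)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_t = np.maximum(0.0, (s2 - m) / (m**2))
    phi_t = phi_t[m > 1]
    if phi_t.empty:
        raise ValueError("no transcript with mean count > 1")
    return float(phi_t.median())


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    if phi <= 0:
        from scipy.stats import poisson

        return poisson.logpmf(k, mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return nbinom.logpmf(k, r, p)


def nb_exact_test(
    counts: pd.DataFrame,
    group_labels: Sequence[str] | pd.Series,
    dispersion: float,
    factors: pd.Series | None = None,
    lib_sizes: pd.Series | None = None,
    group1: str = UNFED,
    group2: str = FED,
    prior_count: float = 0.125,
) -> pd.DataFrame:
    """Two-group exact NB test conditioned on per-transcript totals.

    Counts are scaled by factor x library size to a common effective size
    and summed per group; conditional on the (rounded) total, the two-sided
    p-value sums the probabilities of all splits no more probable than the
    observed one, with group sums NB-distributed (mean proportional to
    group size, dispersion ``dispersion``/n_g; Poisson when the dispersion
    is zero). log2FC is ``group2`` over ``group1`` on normalized group
    means with a prior count.
    """
    labels = pd.Series(np.asarray(group_labels), index=counts.columns)
    s1_cols = labels[labels == group1].index
    s2_cols = labels[labels == group2].index
    n1, n2 = len(s1_cols), len(s2_cols)
    if n1 == 0 or n2 == 0:
        raise ValueError(f"both groups need samples ({group1}: {n1}, {group2}: {n2})")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    eff = effective_library_sizes(counts, factors, lib_sizes)
    common = float(np.exp(np.log(eff).mean()))
    pseudo = counts * (common / eff)
    s1 = pseudo[s1_cols].sum(axis=1).round().astype(np.int64)
    s2 = pseudo[s2_cols].sum(axis=1).round().astype(np.int64)
    pvals = np.ones(len(counts.index))
    for i, (a, b) in enumerate(zip(s1.to_numpy(), s2.to_numpy())):
        pvals[i] = _exact_p(int(a), int(b), n1, n2, dispersion)
    m1 = pseudo[s1_cols].mean(axis=1)
    m2 = pseudo[s2_cols].mean(axis=1)
    log2fc = np.log2((m2 + prior_count) / (m1 + prior_count))
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals}, index=counts.index
    )


def _exact_p(a: int, b: int, n1: int, n2: int, phi: float) -> float:
    t = a + b
    if t == 0:
        return 1.0
    if phi <= 0:
        # Poisson group sums: conditional distribution is binomial.
        k = np.arange(t + 1)
        logp = binom.logpmf(k, t, n1 / (n1 + n2))
        obs = logp[a]
    else:
        mu = t / (n1 + n2)
        k = np.arange(t + 1)
        logp = _nb_logpmf(k, n1 * mu, phi / n1) + _nb_logpmf(
            t - k, n2 * mu, phi / n2
        )
        obs = logp[a]
    logp = logp - logp.max()
    probs = np.exp(logp)
    total = probs.sum()
    p = probs[probs <= probs[a] * (1.0 + 1e-10)].sum() / total
    return float(min(1.0, p))


def bh_adjust(pvals: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def classify_de(de: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Attach FDR and direction labels (up_fed / up_unfed / ns)."""
    out = de.copy()
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    direction = np.where(
        (out["fdr"] < alpha) & (out["log2fc"] > 0),
        "up_fed",
        np.where((out["fdr"] < alpha) & (out["log2fc"] < 0), "up_unfed", "ns"),
    )
    out["direction"] = direction
    return out


def de_counts(de: pd.DataFrame) -> dict[str, int]:
    vc = de["direction"].value_counts()
    n_up_fed = int(vc.get("up_fed", 0))
    n_up_unfed = int(vc.get("up_unfed", 0))
    return {
        "n_total": int(len(de)),
        "n_de": n_up_fed + n_up_unfed,
        "n_up_fed": n_up_fed,
        "n_up_unfed": n_up_unfed,
    }
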