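"""Rank-based group comparison and box-plot summaries.

The assay compares channel-expressing and control cohorts per assay panel
with the Kruskal-Wallis omnibus test followed by Dunn's all-pairwise
post-hoc z tests.  Both are implemented here directly from their formulas
(mid-ranks, tie corrections and all), with scipy supplying only the
chi-square and normal reference distributions; this keeps every constant of
the computation explicit and testable against enumeration oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .exceptions import EmptyGroupError

__all__ = [
    "DunnPair",
    "GroupComparison",
    "SummaryRow",
    "rank_with_ties",
    "kruskal_wallis",
    "dunn_all_pairwise",
    "compare_groups",
    "summarize",
    "format_mean_sd_n",
]


def rank_with_ties(values: Sequence[float]) -> np.ndarray:
    """Mid-ranks (1-based); tied values share the average of their ranks.

    The rank sum is always N(N+1)/2.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise EmptyGroupError("cannot rank an empty sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_term(pooled_ranks_source: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(pooled_ranks_source, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H, its df (k-1) and chi-square p value.

    H = [12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)] / [1 - sum(t^3-t)/(N^3-N)].
    If every pooled value is identical the correction denominator vanishes;
    H is then defined as 0 with p = 1.
    """
    if len(groups) < 2:
        raise EmptyGroupError("need at least 2 groups")
    sizes = [len(g) for g in groups]
    if any(n == 0 for n in sizes):
        raise EmptyGroupError("every group must be nonempty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = pooled.size
    ranks = rank_with_ties(pooled)
    df = len(groups) - 1
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction == 0.0:  # all values identical
        return 0.0, df, 1.0
    h_raw = 0.0
    start = 0
    for n_i in sizes:
        r_i = float(ranks[start : start + n_i].sum())
        h_raw += r_i**2 / n_i
        start += n_i
    h_raw = 12.0 / (n_total * (n_total + 1)) * h_raw - 3.0 * (n_total + 1)
    h = h_raw / correction
    p = float(_sps.chi2.sf(h, df))
    return float(h), df, p


@dataclass(frozen=True)
class DunnPair:
    """One pairwise post-hoc comparison."""

    group_a: str
    group_b: str
    z: float
    p_unadjusted: float
    p_adjusted: float


def dunn_all_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: str = "bonferroni",
) -> list[DunnPair]:
    """Dunn's z tests for every pair of groups, on the pooled mid-ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - sum(t^3-t)/(12(N-1)))
                                     * (1/n_i + 1/n_j)]

    Two-sided p from the standard normal; ``bonferroni`` multiplies by the
    number of comparisons m = k(k-1)/2 (capped at 1), ``none`` leaves p as is.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if len(groups) < 2:
        raise EmptyGroupError("need at least 2 groups")
    sizes = [len(g) for g in groups]
    if any(n == 0 for n in sizes):
        raise EmptyGroupError("every group must be nonempty")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = pooled.size
    ranks = rank_with_ties(pooled)
    mean_ranks = []
    start = 0
    for n_i in sizes:
        mean_ranks.append(float(ranks[start : start + n_i].mean()))
        start += n_i
    var_base = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n_total - 1))
    k = len(groups)
    m = k * (k - 1) // 2
    pairs: list[DunnPair] = []
    for i, j in combinations(range(k), 2):
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if denom == 0.0:  # all pooled values identical
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / denom
        p = float(2.0 * _sps.norm.sf(abs(z)))
        p_adj = min(1.0, m * p) if adjust == "bonferroni" else p
        pairs.append(DunnPair(labels[i], labels[j], float(z), p, p_adj))
    return pairs


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus + post-hoc comparison for one assay panel."""

    assay: str
    groups: tuple[tuple[str, int], ...]  # (label, n)
    h: float
    df: int
    p_omnibus: float
    pairs: tuple[DunnPair, ...]


def compare_groups(
    assay: str,
    groups: Mapping[str, Sequence[float]],
    adjust: str = "bonferroni",
) -> GroupComparison:
    """Kruskal-Wallis followed by Dunn's all-pairwise test on labelled groups."""
    labels = list(groups.keys())
    data = [np.asarray(groups[lab], dtype=float) for lab in labels]
    h, df, p = kruskal_wallis(data)
    pairs = dunn_all_pairwise(data, labels=labels, adjust=adjust)
    return GroupComparison(
        assay=assay,
        groups=tuple((lab, len(d)) for lab, d in zip(labels, data)),
        h=h,
        df=df,
        p_omnibus=p,
        pairs=tuple(pairs),
    )


@dataclass(frozen=True)
class SummaryRow:
    """Box-plot style summary of one construct x assay cohort.

    Quartiles use inclusive linear interpolation.  Outliers are flagged only
    above the box (> q3 + 1.5 IQR); the lower whisker is simply the minimum.
    """

    construct: str
    assay: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    upper_outliers: tuple[float, ...]


def summarize(values: Iterable[float], construct: str = "", assay: str = "") -> SummaryRow:
    """Mean +/- sample SD, quartiles and the asymmetric-outlier whiskers."""
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise EmptyGroupError("cannot summarize an empty sample")
    q1, med, q3 = (float(v) for v in np.percentile(x, [25, 50, 75], method="linear"))
    cutoff = q3 + 1.5 * (q3 - q1)
    outliers = tuple(sorted(float(v) for v in x[x > cutoff]))
    inside = x[x <= cutoff]
    return SummaryRow(
        construct=construct,
        assay=assay,
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else float("nan"),
        median=med,
        q1=q1,
        q3=q3,
        whisker_low=float(x.min()),
        whisker_high=float(inside.max()),
        upper_outliers=outliers,
    )


def format_mean_sd_n(mean: float, sd: float, n: int, decimals: int = 1) -> str:
    """Render a cohort as ``mean ± sd (n)`` with one decimal on the 1e-6 scale."""
    m = round(mean, decimals) + 0.0  # normalize -0.0
    if np.isnan(sd):
        return f"{m:.{decimals}f} (n={n})"
    s = round(sd, decimals) + 0.0
    return f"{m:.{decimals}f} ± {s:.{decimals}f} ({n})"
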