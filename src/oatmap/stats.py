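"""Inferential statistics: recessive segregation goodness-of-fit and
Wilcoxon rank-sum comparisons with summary tables.

The segregation test is a Pearson chi-square against an expected
(mutant : other) ratio — 1:3 for a fully penetrant recessive monogenic
trait in an F2 — with one degree of freedom and no continuity
correction.  The Wilcoxon rank-sum test computes an exact permutation
p-value (midranks for ties) when the combined sample is small and falls
back to a tie-corrected normal approximation with continuity correction
otherwise.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb, erf, sqrt
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class SegregationTest:
    statistic: float
    df: int
    pvalue: float
    n_mutant: int
    n_total: int
    ratio: tuple[int, int]


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # rank sum of the first sample (midranks)
    pvalue: float
    method: str  # "exact" or "normal"


def segregation_chisq(
    n_mutant: int, n_total: int, ratio: tuple[int, int] = (1, 3)
) -> SegregationTest:
    """Pearson chi-square for a two-category segregation ratio.

    ``ratio`` is the expected (mutant : other) pair; scaling it leaves
    the statistic unchanged. No Yates continuity correction is applied.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_mutant <= n_total:
        raise ValueError("n_mutant must lie in [0, n_total]")
    a, b = ratio
    if a <= 0 or b <= 0:
        raise ValueError("ratio components must be positive")
    expected = np.array([a, b], dtype=float) * n_total / (a + b)
    observed = np.array([n_mutant, n_total - n_mutant], dtype=float)
    statistic, pvalue = sps.chisquare(observed, expected)
    return SegregationTest(
        statistic=float(statistic),
        df=1,
        pvalue=float(pvalue),
        n_mutant=n_mutant,
        n_total=n_total,
        ratio=ratio,
    )


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_rank_sum_p(ranks: np.ndarray, n_x: int, w_obs: float) -> float:
    """Exact two-sided p for the rank sum of a size-``n_x`` subset.

    Dynamic programming over the subset-sum distribution of the (doubled,
    hence integer) midranks; equivalent to full enumeration of all
    C(n, n_x) assignments. Two-sided by doubling the smaller tail,
    capped at 1.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    # counts[k][s] = number of size-k subsets with doubled-rank sum s
    counts = np.zeros((n_x + 1, total + 1))
    counts[0, 0] = 1.0
    for r in doubled:
        for k in range(n_x, 0, -1):  # downward: each item used at most once
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    dist = counts[n_x]
    n_subsets = comb(len(ranks), n_x)
    assert abs(dist.sum() - n_subsets) < 1e-6 * n_subsets
    w2 = int(round(2 * w_obs))
    p_le = dist[: w2 + 1].sum() / n_subsets
    p_ge = dist[w2:].sum() / n_subsets
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 25
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact permutation p (midranks for ties) when len(x)+len(y) <=
    ``exact_max_n``; otherwise a normal approximation with tie-corrected
    variance and a 0.5 continuity correction. If all values across both
    groups are identical the p-value is 1 (with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    n_x, n_y = len(x), len(y)
    n = n_x + n_y
    w = float(ranks[:n_x].sum())
    if np.all(combined == combined[0]):
        warnings.warn("all values identical across both groups; p = 1")
        return WilcoxonResult(statistic=w, pvalue=1.0, method="degenerate")
    if n <= exact_max_n:
        return WilcoxonResult(
            statistic=w, pvalue=_exact_rank_sum_p(ranks, n_x, w), method="exact"
        )
    mean = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        warnings.warn("zero rank variance; p = 1")
        return WilcoxonResult(statistic=w, pvalue=1.0, method="degenerate")
    # continuity correction: shrink the deviation by 0.5 toward the mean
    z = (w - mean - 0.5 * np.sign(w - mean)) / sqrt(var)
    p = min(1.0, 2.0 * (1.0 - 0.5 * (1.0 + erf(abs(z) / sqrt(2.0)))))
    return WilcoxonResult(statistic=w, pvalue=float(p), method="normal")


def summary_table(groups: dict[str, Sequence[float]]):
    """Per-group n / mean / sample SD plus pairwise Wilcoxon p-values.

    Returns ``(summary, pvalues)`` where ``summary`` is a DataFrame
    indexed by group label and ``pvalues`` maps each unordered label pair
    to a two-sided rank-sum p. With a single group no p-values are
    computed.
    """
    import pandas as pd

    rows = []
    for label, values in groups.items():
        v = np.asarray(values, dtype=float)
        if len(v) < 1:
            raise ValueError(f"group {label!r} is empty")
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
        rows.append((label, len(v), float(np.mean(v)), sd))
    summary = pd.DataFrame(rows, columns=["group", "n", "mean", "sd"]).set_index(
        "group"
    )
    pvalues: dict[tuple[str, str], float] = {}
    labels = list(groups)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if len(groups[a]) >= 2 and len(groups[b]) >= 2:
                pvalues[(a, b)] = wilcoxon_rank_sum(groups[a], groups[b]).pvalue
    return summary, pvalues
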