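"""Kruskal–Wallis omnibus test and Dunn's pairwise post hoc comparisons.

Both statistics are computed from midranks of the pooled sample with the
standard tie corrections:

    H  = [12 / (N(N+1))] * sum_i n_i (Rbar_i - (N+1)/2)^2
    H' = H / (1 - sum(t^3 - t) / (N^3 - N))          (ties)
    z_ij = (Rbar_i - Rbar_j) /
           sqrt([N(N+1)/12 - sum(t^3 - t)/(12(N-1))] (1/n_i + 1/n_j))

The omnibus p comes from the chi-square approximation with k-1 df (the
standard choice at the group sizes of a typical exposure design; a guideline
minimum is n_i >= 5). An exhaustive-permutation p is available via
``method="exact"`` for small pooled samples. Dunn p-values are two-sided
normal tails, optionally Holm- or Bonferroni-adjusted over all k(k-1)/2
pairs, and mapped to the conventional significance stars
(* p<0.05, ** p<0.01, *** p<0.001, strict inequalities).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ADJUSTMENTS = ("none", "bonferroni", "holm")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    pvalue: float
    n_total: int
    group_sizes: tuple[int, ...]
    tie_correction: float
    method: str = "asymptotic"


@dataclass(frozen=True)
class DunnComparison:
    group_i: str
    group_j: str
    z: float
    pvalue: float
    pvalue_adjusted: float
    stars: str


def significance_stars(p: float) -> str:
    """Map a p-value to the star convention with strict band boundaries."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _pooled_midranks(groups: Sequence[np.ndarray]):
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    splits = np.cumsum(sizes)[:-1]
    return pooled, np.split(ranks, splits), sizes


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def _h_statistic(groups: Sequence[np.ndarray]) -> tuple[float, float, int, list[int]]:
    pooled, rank_groups, sizes = _pooled_midranks(groups)
    n = len(pooled)
    mean_rank = (n + 1) / 2.0
    h = 12.0 / (n * (n + 1)) * sum(
        len(r) * (r.mean() - mean_rank) ** 2 for r in rank_groups
    )
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    return h, correction, n, sizes


def kruskal_wallis(groups: Sequence, *, method: str = "asymptotic") -> TestResult:
    """Tie-corrected Kruskal–Wallis test across k >= 2 groups.

    ``method="exact"`` replaces the chi-square tail with the exhaustive
    permutation probability P(H' >= observed) over all distinct assignments
    of the pooled values to the group sizes (feasible for N <= ~12).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    h, correction, n, sizes = _h_statistic(groups)
    if n < 3:
        raise ValueError("need a pooled sample of at least 3")
    df = len(groups) - 1
    if correction == 0.0:  # every pooled value identical
        return TestResult(0.0, df, 1.0, n, tuple(sizes), 0.0, method)
    h_corr = h / correction
    if method == "asymptotic":
        p = float(stats.chi2.sf(h_corr, df))
    elif method == "exact":
        p = _exact_permutation_p(np.concatenate(groups), sizes, h_corr)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(float(h_corr), df, p, n, tuple(sizes), correction, method)


def _assignments(n: int, sizes: Sequence[int]):
    """Distinct index partitions of range(n) into ordered groups of given sizes."""
    indices = frozenset(range(n))

    def rec(remaining: frozenset, k: int):
        if k == len(sizes) - 1:
            yield (tuple(sorted(remaining)),)
            return
        for combo in itertools.combinations(sorted(remaining), sizes[k]):
            for rest in rec(remaining.difference(combo), k + 1):
                yield (combo,) + rest

    yield from rec(indices, 0)


def _exact_permutation_p(pooled: np.ndarray, sizes: Sequence[int], h_obs: float) -> float:
    n = len(pooled)
    if n > 12:
        raise ValueError("exact method is limited to pooled samples of N <= 12")
    count = 0
    total = 0
    for assignment in _assignments(n, sizes):
        groups = [pooled[list(idx)] for idx in assignment]
        h, corr, _, _ = _h_statistic(groups)
        h_corr = h / corr if corr > 0 else 0.0
        if h_corr >= h_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def dunn_posthoc(
    groups: Sequence,
    labels: Sequence[str] | None = None,
    adjustment: str = "none",
) -> list[DunnComparison]:
    """Dunn's rank-based pairwise comparisons for all k(k-1)/2 pairs.

    The default applies no multiplicity adjustment (the most literal reading
    of a bare "Dunn's post hoc test"); Holm or Bonferroni can be selected.
    """
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"adjustment must be one of {ADJUSTMENTS}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    pooled, rank_groups, sizes = _pooled_midranks(groups)
    n = len(pooled)
    variance = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1))
    pairs = list(itertools.combinations(range(len(groups)), 2))
    zs, praws = [], []
    for i, j in pairs:
        se = math.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (rank_groups[i].mean() - rank_groups[j].mean()) / se
        zs.append(z)
        praws.append(float(2.0 * stats.norm.sf(abs(z))))
    if adjustment == "none":
        padj = list(praws)
    else:
        padj = list(multipletests(praws, method=adjustment)[1])
    return [
        DunnComparison(labels[i], labels[j], z, p, pa, significance_stars(pa))
        for (i, j), z, p, pa in zip(pairs, zs, praws, padj)
    ]


def kruskal_dunn_table(
    df: pd.DataFrame,
    *,
    value: str = "value",
    group: str = "treatment",
    within: Sequence[str] = ("tissue", "day", "biomarker"),
    adjustment: str = "none",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run KW + Dunn within every stratum of a long table.

    Returns (omnibus table, pairwise table), mirroring the per-tissue,
    per-day, per-biomarker loops of a multi-endpoint exposure analysis.
    """
    omni_rows, pair_rows = [], []
    for key, stratum in df.groupby(list(within), sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        labels = [g for g in stratum[group].unique()]
        groups = [stratum.loc[stratum[group] == g, value].to_numpy() for g in labels]
        res = kruskal_wallis(groups)
        omni_rows.append(key + (res.statistic, res.df, res.pvalue, significance_stars(res.pvalue)))
        for cmp in dunn_posthoc(groups, labels=labels, adjustment=adjustment):
            pair_rows.append(
                key
                + (cmp.group_i, cmp.group_j, cmp.z, cmp.pvalue, cmp.pvalue_adjusted, cmp.stars)
            )
    omnibus = pd.DataFrame(omni_rows, columns=list(within) + ["H", "df", "p", "stars"])
    pairwise = pd.DataFrame(
        pair_rows,
        columns=list(within) + ["group_i", "group_j", "z", "p_raw", "p_adj", "stars"],
    )
    return omnibus, pairwise
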