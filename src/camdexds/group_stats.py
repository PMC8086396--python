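"""Rank-based comparison of scores across diagnostic groups.

Kruskal-Wallis tests (tie-corrected, chi-squared reference with k-1
degrees of freedom) with the epsilon-squared effect size H/(n-1), and
Dunn's post-hoc pairwise tests on mean ranks with Bonferroni correction
over all k(k-1)/2 pairs.  Scores are small integers with heavy ties, so
average ranks and the pooled tie correction are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupTestResult",
    "PairwiseResult",
    "kruskal_wallis",
    "epsilon_squared",
    "dunn_posthoc",
    "group_score_tests",
]


@dataclass(frozen=True)
class GroupTestResult:
    """Kruskal-Wallis H (reported as chi-squared), df, p and epsilon-squared."""

    statistic_h: float
    df: int
    p_value: float
    epsilon_squared: float
    n_total: int


@dataclass(frozen=True)
class PairwiseResult:
    """One Dunn pairwise comparison with raw and Bonferroni-adjusted p."""

    group_i: str
    group_j: str
    z_statistic: float
    p_raw: float
    p_adjusted: float


def _check_samples(samples: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(samples) < 2:
        raise ValueError(f"need at least 2 groups, got {len(samples)}")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise ValueError(f"group {i} has 0 observations")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("pooled sample size must be at least 3")
    return arrays


def epsilon_squared(h: float, n_total: int) -> float:
    """Effect size for the Kruskal-Wallis test: H/(n-1), clipped to [0, 1]."""
    if n_total < 2:
        raise ValueError(f"n_total must be >= 2, got {n_total}")
    if h < 0:
        raise ValueError(f"H must be non-negative, got {h}")
    return float(np.clip(h / (n_total - 1), 0.0, 1.0))


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis test across groups.

    All pooled values identical is returned as H=0, p=1 (no evidence of
    any difference), not treated as an error.
    """
    arrays = _check_samples(samples)
    n_total = sum(a.size for a in arrays)
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupTestResult(0.0, df, 1.0, 0.0, n_total)
    h, p = stats.kruskal(*arrays)
    return GroupTestResult(float(h), df, float(p), epsilon_squared(float(h), n_total), n_total)


def dunn_posthoc(
    samples: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> list[PairwiseResult]:
    """Dunn's test on pooled mean ranks for every unordered pair of groups.

    z = (mean-rank difference) / sqrt(A * (1/n_i + 1/n_j)) with
    A = N(N+1)/12 - sum(t^3 - t)/(12(N-1)) pooling all tie groups; p is
    two-sided normal and the Bonferroni factor is the number of pairs.
    """
    arrays = _check_samples(samples)
    k = len(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels must match the number of groups")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    a_factor = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    m = k * (k - 1) // 2
    results = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(a_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0.0:  # every pooled value tied
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        results.append(
            PairwiseResult(labels[i], labels[j], float(z), p_raw, min(1.0, m * p_raw))
        )
    return results


def group_score_tests(
    scored: pd.DataFrame,
    variables: Sequence[str],
    group_column: str = "diagnostic_group",
    group_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kruskal-Wallis + Dunn for each variable across the groups of a cohort.

    Returns two tidy frames: one row per variable (H, df, p, eps^2, n) and
    one row per variable x pair (z, raw and adjusted p).  Non-numeric
    variables (e.g. sex) must be numerically coded by the caller.
    """
    if group_order is None:
        group_order = list(pd.unique(scored[group_column]))
    groups = [scored.loc[scored[group_column] == g, list(variables)] for g in group_order]
    present = [(g, frame) for g, frame in zip(group_order, groups) if len(frame)]
    if len(present) < 2:
        raise ValueError("need at least 2 non-empty groups for group tests")
    test_rows, pair_rows = [], []
    for var in variables:
        samples = [frame[var].to_numpy(dtype=float) for _, frame in present]
        labels = [g for g, _ in present]
        res = kruskal_wallis(samples)
        test_rows.append(
            {
                "variable": var,
                "statistic_h": res.statistic_h,
                "df": res.df,
                "p_value": res.p_value,
                "epsilon_squared": res.epsilon_squared,
                "n_total": res.n_total,
            }
        )
        for pr in dunn_posthoc(samples, labels):
            pair_rows.append(
                {
                    "variable": var,
                    "group_i": pr.group_i,
                    "group_j": pr.group_j,
                    "z_statistic": pr.z_statistic,
                    "p_raw": pr.p_raw,
                    "p_adjusted": pr.p_adjusted,
                }
            )
    return pd.DataFrame(test_rows), pd.DataFrame(pair_rows)
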