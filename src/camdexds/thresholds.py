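"""Diagnostic cut-off derivation: empirical ROC, Youden index, intervals.

The positivity convention throughout is "score strictly greater than the
cut-off".  Candidate cut-offs are the midpoints between consecutive
distinct observed scores, plus sentinels below the minimum and above the
maximum; on integer scores this yields the half-integer cut-offs the
method reports (e.g. total > 7.5).

The AUC is the probability that a randomly chosen positive outscores a
randomly chosen negative, ties counted half (the rank-sum / trapezoidal
identity).  For high AUCs (> 0.90) the confidence interval treats the
AUC as a proportion and applies the Wilson score interval at a
configurable effective n; otherwise an asymptotic DeLong interval is
used.  The interval method actually applied is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import SCORE_FIELDS, CodificationError

__all__ = [
    "RocCurve",
    "RocThresholdResult",
    "empirical_roc",
    "auc",
    "youden_cutoff",
    "wilson_interval",
    "delong_interval",
    "derive_threshold",
    "threshold_table",
]


@dataclass(frozen=True)
class RocCurve:
    """Sensitivity/specificity at every candidate cut-off."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    positive_label: str = "positive"
    negative_label: str = "negative"


@dataclass(frozen=True)
class RocThresholdResult:
    """A derived diagnostic threshold with its operating characteristics.

    ``youden_max`` is on the percent scale, 100 * (sens + spec - 1) at the
    chosen cut-off.
    """

    auc: float
    ci_low: float
    ci_high: float
    ci_method: str
    cutoff: float
    youden_max: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    n_positive: int
    n_negative: int
    effective_n: int


def _as_groups(scores_positive, scores_negative) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be non-empty")
    return pos, neg


def empirical_roc(
    scores_positive,
    scores_negative,
    positive_label: str = "positive",
    negative_label: str = "negative",
) -> RocCurve:
    """Empirical ROC over midpoint cut-offs of the pooled distinct scores."""
    pos, neg = _as_groups(scores_positive, scores_negative)
    values = np.unique(np.concatenate([pos, neg]))
    mids = (values[:-1] + values[1:]) / 2.0
    thresholds = np.concatenate([[values[0] - 0.5], mids, [values[-1] + 0.5]])
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    return RocCurve(thresholds, sens, spec, positive_label, negative_label)


def auc(scores_positive, scores_negative) -> float:
    """P(positive > negative) with half credit for ties, via pooled ranks."""
    pos, neg = _as_groups(scores_positive, scores_negative)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def youden_cutoff(
    curve: RocCurve, tie_break: str = "smallest"
) -> tuple[float, float, float, float]:
    """Cut-off maximising Youden's J = sens + spec - 1 on the curve.

    Returns (cutoff, J, sens, spec) with J on the [0, 1] scale.  When
    several cut-offs attain the maximum, ``tie_break`` selects the
    smallest (default, favouring sensitivity) or the largest.
    """
    if tie_break not in ("smallest", "largest"):
        raise ValueError(f"tie_break must be 'smallest' or 'largest', got {tie_break!r}")
    j = curve.sensitivity + curve.specificity - 1.0
    j_max = j.max()
    candidates = np.flatnonzero(j >= j_max - 1e-12)
    idx = candidates[0] if tie_break == "smallest" else candidates[-1]
    return (
        float(curve.thresholds[idx]),
        float(j[idx]),
        float(curve.sensitivity[idx]),
        float(curve.specificity[idx]),
    )


def wilson_interval(
    p_hat: float, effective_n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a proportion.

    Bounds are the roots of inverting the score test:
    (p + z^2/2n +/- z * sqrt(p(1-p)/n + z^2/4n^2)) / (1 + z^2/n).
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat must be in [0, 1], got {p_hat}")
    if effective_n < 1:
        raise ValueError(f"effective_n must be >= 1, got {effective_n}")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    z = stats.norm.ppf((1.0 + confidence) / 2.0)
    n = float(effective_n)
    denom = 1.0 + z * z / n
    centre = (p_hat + z * z / (2.0 * n)) / denom
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n + z * z / (4.0 * n * n)) / denom
    # the interval contains p_hat mathematically; enforce it against
    # floating-point residue at the extremes (e.g. sqrt((z/2n)^2) != z/2n)
    low = float(min(max(0.0, centre - half), p_hat))
    high = float(max(min(1.0, centre + half), p_hat))
    return low, high


def delong_interval(
    scores_positive, scores_negative, confidence: float = 0.95
) -> tuple[float, float]:
    """Asymptotic rank-based (DeLong) interval for the AUC.

    Uses the placement-value variance estimator: var(AUC) =
    var(V10)/n_pos + var(V01)/n_neg, where V10_i is the placement of
    positive i among the negatives and vice versa.
    """
    pos, neg = _as_groups(scores_positive, scores_negative)
    # placement matrix: 1 if pos > neg, 0.5 on ties
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    theta = cmp.mean()
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    var = 0.0
    if pos.size > 1:
        var += np.var(v10, ddof=1) / pos.size
    if neg.size > 1:
        var += np.var(v01, ddof=1) / neg.size
    z = stats.norm.ppf((1.0 + confidence) / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, theta - half)), float(min(1.0, theta + half))


def derive_threshold(
    scored: pd.DataFrame,
    positive_group: str,
    negative_group: str,
    score_field: str = "total",
    group_column: str = "diagnostic_group",
    effective_n: int | None = None,
    confidence: float = 0.95,
    wilson_above: float = 0.90,
    tie_break: str = "smallest",
) -> RocThresholdResult:
    """Derive the diagnostic cut-off for one group-vs-group comparison.

    ``scored`` is a scored-cohort frame (see ``score_cohort``).  The
    Wilson interval is applied when the AUC exceeds ``wilson_above``;
    ``effective_n`` defaults to the number of rows in the full frame
    (the whole cohort, not only the two compared groups), which is how
    the reference intervals for this instrument were computed; pass the
    two-group size to make the interval comparison-local.
    """
    if score_field not in SCORE_FIELDS or score_field not in scored.columns:
        raise CodificationError(f"unknown score field {score_field!r}")
    for g in (positive_group, negative_group):
        if not (scored[group_column] == g).any():
            raise CodificationError(f"group {g!r} absent from cohort")
    pos = scored.loc[scored[group_column] == positive_group, score_field].to_numpy(float)
    neg = scored.loc[scored[group_column] == negative_group, score_field].to_numpy(float)
    curve = empirical_roc(pos, neg, positive_group, negative_group)
    area = auc(pos, neg)
    cutoff, j, sens, spec = youden_cutoff(curve, tie_break=tie_break)
    n_eff = int(effective_n) if effective_n is not None else int(len(scored))
    if area > wilson_above:
        lo, hi = wilson_interval(area, n_eff, confidence)
        method = "wilson"
    else:
        lo, hi = delong_interval(pos, neg, confidence)
        method = "delong"
    # an interval for a point estimate must cover it
    lo, hi = min(lo, area), max(hi, area)
    return RocThresholdResult(
        auc=area,
        ci_low=lo,
        ci_high=hi,
        ci_method=method,
        cutoff=cutoff,
        youden_max=100.0 * j,
        sens_at_cutoff=sens,
        spec_at_cutoff=spec,
        n_positive=pos.size,
        n_negative=neg.size,
        effective_n=n_eff,
    )


def threshold_table(
    scored: pd.DataFrame,
    comparisons,
    score_fields=SCORE_FIELDS,
    **kwargs,
) -> pd.DataFrame:
    """One row per (positive group, negative group, score field)."""
    rows = []
    for positive_group, negative_group in comparisons:
        for field in score_fields:
            res = derive_threshold(
                scored, positive_group, negative_group, field, **kwargs
            )
            rows.append(
                {
                    "positive_group": positive_group,
                    "negative_group": negative_group,
                    "score_field": field,
                    "auc": res.auc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "ci_method": res.ci_method,
                    "cutoff": res.cutoff,
                    "youden_max": res.youden_max,
                    "sens_at_cutoff": res.sens_at_cutoff,
                    "spec_at_cutoff": res.spec_at_cutoff,
                    "n_positive": res.n_positive,
                    "n_negative": res.n_negative,
                    "effective_n": res.effective_n,
                }
            )
    return pd.DataFrame(rows)
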