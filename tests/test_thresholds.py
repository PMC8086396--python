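"""ROC derivation, AUC, Youden cut-offs and interval estimates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camdexds.scoring import CodificationError
from camdexds.thresholds import (
    auc,
    delong_interval,
    derive_threshold,
    empirical_roc,
    threshold_table,
    wilson_interval,
    youden_cutoff,
)


def brute_force_auc(pos, neg):
    return np.mean([
        1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg
    ])


def brute_force_best_cutoff(pos, neg):
    """Exhaustive search over every midpoint between distinct pooled values."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    values = np.unique(np.concatenate([pos, neg]))
    cuts = np.concatenate([[values[0] - 0.5],
                           (values[:-1] + values[1:]) / 2,
                           [values[-1] + 0.5]])
    best = None
    for c in cuts:
        j = (pos > c).mean() + (neg <= c).mean() - 1.0
        if best is None or j > best[1] + 1e-12:
            best = (c, j)
    return best


scores = st.lists(st.integers(0, 12), min_size=1, max_size=10)


class TestEmpiricalRoc:
    def test_perfect_separation_has_perfect_point(self):
        curve = empirical_roc([8, 30], [0, 1])
        j = curve.sensitivity + curve.specificity - 1.0
        assert j.max() == pytest.approx(1.0)

    def test_indistinguishable_groups(self):
        curve = empirical_roc([1], [1])
        assert (curve.sensitivity + curve.specificity - 1.0).max() == pytest.approx(0.0)

    def test_monotone_endpoints(self):
        curve = empirical_roc([3, 5, 5, 9], [1, 3, 4])
        assert np.all(np.diff(curve.sensitivity) <= 1e-12)
        assert np.all(np.diff(curve.specificity) >= -1e-12)
        assert (curve.sensitivity[0], curve.specificity[0]) == (1.0, 0.0)
        assert (curve.sensitivity[-1], curve.specificity[-1]) == (0.0, 1.0)

    def test_sens_spec_match_exhaustive_counting(self):
        pos, neg = [3, 5, 5, 9], [1, 3, 4]
        curve = empirical_roc(pos, neg)
        for t, s, sp in zip(curve.thresholds, curve.sensitivity, curve.specificity):
            assert s == pytest.approx(np.mean(np.asarray(pos) > t))
            assert sp == pytest.approx(np.mean(np.asarray(neg) <= t))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            empirical_roc([], [1])


class TestAuc:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([2, 3], [0, 1], 1.0),
            ([5, 5, 5], [5, 5, 5], 0.5),
            ([3, 5, 9], [1, 4, 5], 6.5 / 9),  # brute-force pairwise count
        ],
    )
    def test_known_values(self, pos, neg, expected):
        assert auc(pos, neg) == pytest.approx(expected)

    @given(pos=scores, neg=scores)
    @settings(max_examples=200, deadline=None)
    def test_equals_exhaustive_pairwise_probability(self, pos, neg):
        assert auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    @given(pos=scores, neg=scores)
    @settings(max_examples=50, deadline=None)
    def test_swap_symmetry_and_monotone_invariance(self, pos, neg):
        a = auc(pos, neg)
        assert auc(neg, pos) == pytest.approx(1.0 - a, abs=1e-12)
        f = lambda v: [3 * x**2 + 1 for x in v]  # strictly increasing on x >= 0
        assert auc(f(pos), f(neg)) == pytest.approx(a, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        pos = rng.integers(0, 30, size=40)
        neg = rng.integers(0, 20, size=60)
        y = np.r_[np.ones(40), np.zeros(60)]
        assert auc(pos, neg) == pytest.approx(
            roc_auc_score(y, np.r_[pos, neg]), abs=1e-12
        )


class TestYoudenCutoff:
    def test_perfect_separation_forces_midpoint(self):
        curve = empirical_roc([10, 12], [2, 4])
        cutoff, j, sens, spec = youden_cutoff(curve)
        assert j == pytest.approx(1.0)
        assert cutoff == pytest.approx(7.0)  # midpoint of 4 and 10
        assert (sens, spec) == (1.0, 1.0)

    @given(pos=scores, neg=scores)
    @settings(max_examples=150, deadline=None)
    def test_matches_exhaustive_search(self, pos, neg):
        curve = empirical_roc(pos, neg)
        cutoff, j, sens, spec = youden_cutoff(curve)
        bf_cut, bf_j = brute_force_best_cutoff(pos, neg)
        assert j == pytest.approx(bf_j, abs=1e-12)
        assert cutoff == pytest.approx(bf_cut)  # same smallest-cut tie rule
        assert j == pytest.approx(sens + spec - 1.0, abs=1e-12)

    def test_scaling_scores_scales_cutoff(self):
        pos, neg = [3, 5, 5, 9], [1, 3, 4]
        c1, j1, s1, sp1 = youden_cutoff(empirical_roc(pos, neg))
        c2, j2, s2, sp2 = youden_cutoff(
            empirical_roc([2 * x for x in pos], [2 * x for x in neg])
        )
        assert (j1, s1, sp1) == (j2, s2, sp2)
        assert c2 == pytest.approx(2 * c1)

    def test_tie_break_largest(self):
        curve = empirical_roc([1], [1])  # J = 0 everywhere
        small = youden_cutoff(curve, tie_break="smallest")[0]
        large = youden_cutoff(curve, tie_break="largest")[0]
        assert small < large


class TestWilsonInterval:
    # AUC point estimates printed with their 95% intervals at n = 85
    @pytest.mark.parametrize(
        "p_hat, lo, hi",
        [
            (0.954, 0.887, 0.982),
            (0.958, 0.892, 0.984),
            (0.946, 0.876, 0.978),
            (0.994, 0.946, 0.999),
            (0.992, 0.943, 0.999),
        ],
    )
    def test_reported_intervals(self, p_hat, lo, hi):
        low, high = wilson_interval(p_hat, 85)
        assert low == pytest.approx(lo, abs=5e-4)
        assert high == pytest.approx(hi, abs=5e-4)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for p_hat, n in [(0.3, 40), (0.95, 85), (0.5, 10)]:
            lo, hi = wilson_interval(p_hat, n)
            sm_lo, sm_hi = proportion_confint(p_hat * n, n, method="wilson")
            assert lo == pytest.approx(sm_lo, abs=1e-10)
            assert hi == pytest.approx(sm_hi, abs=1e-10)

    @given(p=st.floats(0, 1), n=st.integers(1, 10**6))
    @settings(max_examples=100, deadline=None)
    def test_contains_estimate_within_unit_interval(self, p, n):
        lo, hi = wilson_interval(p, n)
        assert 0.0 <= lo <= p <= hi <= 1.0

    def test_width_shrinks_with_n_and_degenerate_edges(self):
        widths = [np.diff(wilson_interval(0.5, n))[0] for n in (10, 100, 10**4, 10**8)]
        assert all(w1 > w2 for w1, w2 in zip(widths, widths[1:]))
        assert widths[-1] < 1e-3
        assert wilson_interval(0.0, 50)[0] == 0.0

    @pytest.mark.parametrize("bad", [(-0.1, 10), (1.1, 10), (0.5, 0)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            wilson_interval(*bad)


class TestDeriveThreshold:
    def test_perfectly_separated_cohort(self, default_scored):
        sub = default_scored[default_scored.diagnostic_group.isin(
            ["asymptomatic", "dementia"])]
        res = derive_threshold(sub, "dementia", "asymptomatic", "total")
        assert res.auc > 0.99
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.youden_max == pytest.approx(
            100 * (res.sens_at_cutoff + res.spec_at_cutoff - 1.0)
        )

    def test_wilson_gate_and_effective_n_default(self, default_scored):
        res = derive_threshold(default_scored, "dementia", "asymptomatic", "total")
        assert res.ci_method == "wilson"
        assert res.effective_n == len(default_scored)
        lo, hi = wilson_interval(res.auc, len(default_scored))
        assert res.ci_low == pytest.approx(min(lo, res.auc))
        assert res.ci_high == pytest.approx(max(hi, res.auc))

    def test_delong_used_for_moderate_auc(self, rng):
        import pandas as pd

        frame = pd.DataFrame({
            "diagnostic_group": ["a"] * 50 + ["b"] * 50,
            "total": np.r_[rng.normal(10, 4, 50), rng.normal(12, 4, 50)].round(),
        })
        res = derive_threshold(frame, "b", "a", "total", group_column="diagnostic_group")
        assert res.auc <= 0.90
        assert res.ci_method == "delong"
        assert res.ci_low <= res.auc <= res.ci_high

    def test_unknown_group_or_field(self, default_scored):
        with pytest.raises(CodificationError, match="absent"):
            derive_threshold(default_scored, "nosuch", "asymptomatic", "total")
        with pytest.raises(CodificationError, match="score field"):
            derive_threshold(default_scored, "dementia", "asymptomatic", "sum")

    def test_threshold_table_rows(self, default_scored):
        table = threshold_table(
            default_scored,
            [("dementia", "asymptomatic"), ("prodromal", "asymptomatic")],
            score_fields=["total", "section_b"],
        )
        assert len(table) == 4
        assert set(table.ci_method) <= {"wilson", "delong"}


class TestDelongInterval:
    def test_basic_properties(self, rng):
        pos = rng.normal(3, 1, 40)
        neg = rng.normal(1, 1, 50)
        a = auc(pos, neg)
        lo, hi = delong_interval(pos, neg)
        assert 0.0 <= lo <= a <= hi <= 1.0

    def test_coverage_under_repetition(self):
        """~95% of DeLong intervals should cover the true AUC (normal shift
        model with known theta)."""
        from scipy.stats import norm

        rng = np.random.default_rng(5)
        delta = 1.0
        theta = norm.cdf(delta / np.sqrt(2))
        cover = 0
        reps = 500
        for _ in range(reps):
            pos = rng.normal(delta, 1, 80)
            neg = rng.normal(0, 1, 80)
            lo, hi = delong_interval(pos, neg)
            cover += lo <= theta <= hi
        assert cover / reps == pytest.approx(0.95, abs=0.03)
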