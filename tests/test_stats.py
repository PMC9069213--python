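import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from procad.stats import (
    delong_paired_test,
    fisher_exact_2x2,
    mann_whitney_u,
    roc_and_auc,
    wilson_cc_interval,
)


class TestWilsonCC:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [
            (13, 16, 53.7, 95.0),
            (10, 11, 57.1, 99.5),
            (3, 5, 17.0, 92.7),
        ],
    )
    def test_reference_intervals_to_one_decimal_percent(self, k, n, lo, hi):
        a, b = wilson_cc_interval(k, n, 0.95)
        assert round(a * 100, 1) == lo
        assert round(b * 100, 1) == hi

    def test_zero_successes_clips_lower_bound(self):
        lo, hi = wilson_cc_interval(0, 9, 0.95)
        assert lo == 0.0 and 0 < hi < 1

    def test_all_successes_clips_upper_bound(self):
        lo, hi = wilson_cc_interval(9, 9, 0.95)
        assert hi == 1.0 and 0 < lo < 1

    @given(k=st.integers(0, 30), n=st.integers(1, 30))
    @settings(max_examples=60, deadline=None)
    def test_bounds_ordered_and_contain_point_estimate(self, k, n):
        if k > n:
            return
        lo, hi = wilson_cc_interval(k, n, 0.95)
        assert 0.0 <= lo <= k / n <= hi <= 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            wilson_cc_interval(5, 4)


def trapezoid_auc(scores, labels, low_is_positive=False):
    """Independent AUC oracle: trapezoidal integration of the ROC curve."""
    r = roc_and_auc(scores, labels, low_is_positive)
    pts = [(0.0, 0.0)] + [(fpr, sens) for _, sens, fpr in r.points] + [(1.0, 1.0)]
    pts = sorted(set(pts))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2
    return area


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        r = roc_and_auc(np.array([3.0, 4.0, 1.0, 0.5]), np.array([1, 1, 0, 0], bool))
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        r = roc_and_auc(np.full(8, 2.0), np.array([1, 1, 1, 0, 0, 0, 0, 0], bool))
        assert r.auc == 0.5

    def test_pair_counting_example(self):
        # cases (3.1, 0.5) vs control (1.0): one concordant, one discordant
        r = roc_and_auc(np.array([3.1, 0.5, 1.0]), np.array([1, 1, 0], bool))
        assert r.auc == 0.5

    def test_low_is_positive_orientation(self):
        scores = np.array([5.0, 8.0, 20.0, 25.0])
        labels = np.array([1, 1, 0, 0], bool)
        assert roc_and_auc(scores, labels, low_is_positive=True).auc == 1.0
        assert roc_and_auc(scores, labels, low_is_positive=False).auc == 0.0

    def test_auc_equals_trapezoid_on_random_instances(self, rng):
        for _ in range(200):
            m, n = rng.integers(2, 8, 2)
            scores = np.round(rng.normal(size=m + n), 1)  # ties occur
            labels = np.zeros(m + n, bool)
            labels[:m] = True
            r = roc_and_auc(scores, labels)
            assert r.auc == pytest.approx(trapezoid_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        labels[0] = True
        labels[1] = False
        r = roc_and_auc(scores, labels)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_and_auc(np.array([1.0, 2.0]), np.array([1, 1], bool))

    def test_ci_contains_auc_and_is_clipped(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 20), rng.normal(0, 1, 20)])
        labels = np.zeros(40, bool)
        labels[:20] = True
        r = roc_and_auc(scores, labels)
        assert 0 <= r.auc_ci[0] <= r.auc <= r.auc_ci[1] <= 1


class TestDelongPaired:
    def test_identical_markers_give_p_one(self, rng):
        s = rng.normal(size=30)
        labels = np.zeros(30, bool)
        labels[:12] = True
        a, b, p = delong_paired_test(s, s, labels)
        assert a == b and p == 1.0

    def test_separating_vs_random_marker_significant(self, rng):
        n = 100
        labels = np.zeros(n, bool)
        labels[:50] = True
        good = labels.astype(float) + rng.normal(0, 0.1, n)
        junk = rng.normal(size=n)
        a, b, p = delong_paired_test(good, junk, labels)
        assert a > 0.99 and p < 0.01

    def test_aucs_match_single_marker_computation(self, rng):
        labels = np.zeros(40, bool)
        labels[:15] = True
        s1 = rng.normal(labels.astype(float), 1.0)
        s2 = rng.normal(size=40)
        a, b, _ = delong_paired_test(s1, s2, labels)
        assert a == pytest.approx(roc_and_auc(s1, labels).auc)
        assert b == pytest.approx(roc_and_auc(s2, labels).auc)

    def test_mismatched_samples_rejected(self):
        with pytest.raises(ValueError, match="same samples"):
            delong_paired_test(np.ones(5), np.ones(6), np.zeros(5, bool))


def fisher_enumeration(table):
    """Independent oracle: enumerate all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


class TestFisherExact:
    def test_grade_association_style_table(self):
        assert fisher_exact_2x2([[10, 1], [3, 2]]) == pytest.approx(0.2143, abs=1e-4)

    def test_diagonal_table_closed_form(self):
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(
            2 / math.comb(10, 5), rel=1e-9
        )

    def test_identical_rows_give_one(self):
        assert fisher_exact_2x2([[4, 6], [4, 6]]) == pytest.approx(1.0)

    def test_matches_enumeration_for_small_margins(self, rng):
        for _ in range(80):
            t = rng.integers(0, 9, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact_2x2(t) == pytest.approx(
                fisher_enumeration(t.tolist()), rel=1e-6
            )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [3, 2]])


def mwu_permutation_oracle(x, y):
    """Exact two-sided p by full enumeration of group assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = rankdata(pooled)
    mu = nx * len(y) / 2
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        u = ranks[list(combo)].sum() - nx * (nx + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_maximal_u(self):
        u, p = mann_whitney_u([10, 11, 12], [1, 2, 3])
        assert u == 9  # n_x * n_y
        assert p == pytest.approx(0.1, abs=1e-9)  # smallest attainable at 3v3

    def test_identical_multisets_give_p_near_one(self):
        u, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(1.0)

    def test_small_sample_matches_enumeration(self, rng):
        for _ in range(10):
            x = rng.integers(0, 6, 4).astype(float)  # ties likely
            y = rng.integers(0, 6, 4).astype(float)
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(mwu_permutation_oracle(x, y), rel=1e-9)

    def test_large_sample_uses_tie_corrected_normal(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.normal(0.5, 1, 30)
        y = rng.normal(0.0, 1, 25)
        u, p = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == ref.statistic and p == ref.pvalue

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])
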