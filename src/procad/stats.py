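"""Statistical primitives for diagnostic evaluation.

Implements the evaluation battery used around the aneuploidy classifier:
Wilson score intervals with continuity correction for proportions, ROC
curves with Mann–Whitney (pair-counting) AUC and DeLong variance, the paired
DeLong test for correlated ROC curves, and thin wrappers over scipy for
Fisher's exact and Mann–Whitney U tests (with exact small-sample
enumeration for the latter, which scipy's asymptotic path does not provide
under ties).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "wilson_cc_interval",
    "ROCResult",
    "roc_and_auc",
    "delong_paired_test",
    "fisher_exact_2x2",
    "mann_whitney_u",
]


def wilson_cc_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval with continuity correction for k successes in n.

    The lower bound is clipped to 0 when k == 0 and the upper to 1 when
    k == n (Newcombe's convention).
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise TypeError("k and n must be integers")
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid proportion {k}/{n}")
    z = sps.norm.ppf(1 - (1 - confidence) / 2)
    p = k / n
    q = 1 - p
    denom = 2 * (n + z * z)
    lo = (2 * n * p + z * z - 1 - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * q + 1))) / denom
    hi = (2 * n * p + z * z + 1 + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * q - 1))) / denom
    lo = 0.0 if k == 0 else max(lo, 0.0)
    hi = 1.0 if k == n else min(hi, 1.0)
    return lo, hi


@dataclass
class ROCResult:
    """ROC points, pair-counting AUC and its DeLong confidence interval."""

    points: list[tuple[float, float, float]]  # (cutoff, sensitivity, 1-specificity)
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    low_is_positive: bool = False


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components via midranks; also the AUC itself."""
    m, n = pos.size, neg.size
    # V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i), and symmetrically V01
    v10 = np.empty(m)
    for i, x in enumerate(pos):
        v10[i] = ((neg < x).sum() + 0.5 * (neg == x).sum()) / n
    v01 = np.empty(n)
    for j, y in enumerate(neg):
        v01[j] = ((pos > y).sum() + 0.5 * (pos == y).sum()) / m
    return v10, v01, float(v10.mean())


def roc_and_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    low_is_positive: bool = False,
    confidence: float = 0.95,
) -> ROCResult:
    """ROC at all observed thresholds; AUC by pair counting (ties = 1/2).

    ``labels`` is boolean (True = case).  The decision rule is score >= t,
    or score <= t when ``low_is_positive`` (markers where a low value is
    cancer-like, e.g. the free/total PSA percentage).  The AUC CI uses the
    DeLong variance estimator on the oriented scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    pos_raw, neg_raw = scores[labels], scores[~labels]
    if pos_raw.size == 0 or neg_raw.size == 0:
        raise ValueError("both classes must be present")
    sgn = -1.0 if low_is_positive else 1.0
    pos, neg = sgn * pos_raw, sgn * neg_raw

    v10, v01, auc = _placements(pos, neg)
    m, n = pos.size, neg.size
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = sps.norm.ppf(1 - (1 - confidence) / 2)
    half = z * math.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    points: list[tuple[float, float, float]] = []
    thresholds = np.unique(scores)
    order = thresholds if low_is_positive else thresholds[::-1]
    for t in order:
        called = scores <= t if low_is_positive else scores >= t
        sens = (called & labels).sum() / labels.sum()
        fpr = (called & ~labels).sum() / (~labels).sum()
        points.append((float(t), float(sens), float(fpr)))
    return ROCResult(
        points=points, auc=auc, auc_ci=ci, n_pos=m, n_neg=n, low_is_positive=low_is_positive
    )


def delong_paired_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    low_is_positive_a: bool = False,
    low_is_positive_b: bool = False,
) -> tuple[float, float, float]:
    """Paired DeLong test for two correlated ROC AUCs on the same samples.

    Returns (auc_a, auc_b, two-sided p) using the normal approximation on
    the AUC difference with the DeLong covariance.  Identical markers give
    p = 1.0 by convention (zero variance of a zero difference).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("markers must be scored on the same samples")
    sa = (-1.0 if low_is_positive_a else 1.0) * scores_a
    sb = (-1.0 if low_is_positive_b else 1.0) * scores_b
    pos = labels
    v10a, v01a, auc_a = _placements(sa[pos], sa[~pos])
    v10b, v01b, auc_b = _placements(sb[pos], sb[~pos])
    m, n = int(pos.sum()), int((~pos).sum())
    if m < 2 or n < 2:
        raise ValueError("paired DeLong test needs >= 2 samples per class")
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        p = 1.0 if math.isclose(auc_a, auc_b) else 0.0
    else:
        zstat = (auc_a - auc_b) / math.sqrt(var_diff)
        p = 2 * sps.norm.sf(abs(zstat))
    return auc_a, auc_b, float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (conditional on margins)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def _mwu_exact_enumeration(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by enumerating group assignments.

    Handles ties via midranks; feasible for n_x + n_y <= 12.
    """
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    ranks = sps.rankdata(pooled)
    r_obs = ranks[:nx].sum()
    u_obs = r_obs - nx * (nx + 1) / 2
    mu = nx * (pooled.size - nx) / 2
    dev_obs = abs(u_obs - mu)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(n), nx):
        u = ranks[list(combo)].sum() - nx * (nx + 1) / 2
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            extreme += 1
    return float(u_obs), extreme / total


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann–Whitney U (midranks for ties) with a two-sided p.

    Exact enumeration when n_x + n_y <= 12; otherwise the tie-corrected
    normal approximation via scipy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size + y.size <= 12:
        return _mwu_exact_enumeration(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
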