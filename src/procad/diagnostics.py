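"""The arm-level aneuploidy diagnostic model and its evaluation metrics.

A sample's diagnostic score is the maximum absolute arm Z-score over all
retained autosomal arms; the sample is called positive when the score
reaches the operating cutoff (default |Z| >= 2.50, selected by Youden's
index).  Confusion-matrix metrics carry Wilson continuity-corrected 95%
confidence intervals; percentages are displayed rounded half-up to one
decimal.  An optional combined rule adds the free/total PSA percentage as
an OR-ed second arm of the test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .panel import ArmZProfile
from .stats import wilson_cc_interval

__all__ = [
    "DiagnosisCall",
    "ConfusionCounts",
    "MetricWithCI",
    "DiagnosticMetrics",
    "classify_sample",
    "confusion_metrics",
    "youden_optimal_cutoff",
    "combined_test",
    "percent_display",
]


def percent_display(fraction: float, decimals: int = 1) -> float:
    """Percent value rounded half-up (81.25% -> 81.3)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(fraction) * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DiagnosisCall:
    """max-|Z| diagnostic call for one sample."""

    sample_id: str
    score: float
    cutoff: float
    positive: bool
    contributing_arms: list[str] = field(default_factory=list)


def classify_sample(profile: ArmZProfile, cutoff: float = 2.5) -> DiagnosisCall:
    """Score = max_a |Z_a|; positive iff score >= cutoff (boundary inclusive).

    ``contributing_arms`` is the argmax set — the arms attaining the score.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if profile.n_arms == 0:
        raise ValueError(f"{profile.sample_id}: empty arm Z profile")
    absz = np.abs(profile.z)
    score = float(absz.max())
    arms = [a for a, v in zip(profile.arms, absz) if v == score]
    return DiagnosisCall(
        sample_id=profile.sample_id,
        score=score,
        cutoff=cutoff,
        positive=score >= cutoff,
        contributing_arms=arms,
    )


@dataclass(frozen=True)
class ConfusionCounts:
    tn: int
    tp: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.tp, self.fn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tn + self.tp + self.fn + self.fp


@dataclass(frozen=True)
class MetricWithCI:
    """A proportion k/n with its Wilson continuity-corrected CI."""

    value: float  # fraction in [0, 1]; nan when undefined
    ci: tuple[float, float]
    k: int
    n: int

    @property
    def defined(self) -> bool:
        return self.n > 0

    @property
    def percent(self) -> float:
        return percent_display(self.value) if self.defined else math.nan

    @property
    def percent_ci(self) -> tuple[float, float]:
        return (percent_display(self.ci[0]), percent_display(self.ci[1]))


def _metric(k: int, n: int, confidence: float) -> MetricWithCI:
    if n == 0:
        return MetricWithCI(value=math.nan, ci=(math.nan, math.nan), k=k, n=n)
    return MetricWithCI(value=k / n, ci=wilson_cc_interval(k, n, confidence), k=k, n=n)


@dataclass
class DiagnosticMetrics:
    sensitivity: MetricWithCI
    specificity: MetricWithCI
    ppv: MetricWithCI
    npv: MetricWithCI
    accuracy: MetricWithCI

    @property
    def youden_j(self) -> float:
        return self.sensitivity.value + self.specificity.value - 1

    def to_dict(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            m: MetricWithCI = getattr(self, name)
            out[name] = {
                "fraction": m.value,
                "percent": m.percent,
                "ci95": list(m.ci) if m.defined else None,
                "k": m.k,
                "n": m.n,
            }
        out["youden_j"] = self.youden_j
        return out


def confusion_metrics(c: ConfusionCounts, confidence: float = 0.95) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV/accuracy with Wilson-CC intervals.

    A metric whose denominator is zero is returned as undefined (NaN) rather
    than raising.
    """
    return DiagnosticMetrics(
        sensitivity=_metric(c.tp, c.tp + c.fn, confidence),
        specificity=_metric(c.tn, c.tn + c.fp, confidence),
        ppv=_metric(c.tp, c.tp + c.fp, confidence),
        npv=_metric(c.tn, c.tn + c.fn, confidence),
        accuracy=_metric(c.tp + c.tn, c.total, confidence),
    )


def youden_optimal_cutoff(candidates: list[tuple[float, ConfusionCounts]]) -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1; ties -> larger cutoff.

    The larger cutoff wins ties because it operates at higher specificity.
    """
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate cutoffs")
    best_cut, best_j = None, -math.inf
    for cut, c in candidates:
        m = confusion_metrics(c)
        j = m.youden_j
        if j > best_j or (j == best_j and (best_cut is None or cut > best_cut)):
            best_cut, best_j = cut, j
    return float(best_cut)


def combined_test(
    calls: list[DiagnosisCall],
    ft_psa_percent: list[float | None],
    ft_threshold: float = 16.0,
) -> list[bool]:
    """OR-combination of the CNV call with a low free/total PSA percentage.

    A sample is positive when its CNV call is positive OR its f/t PSA is
    present and strictly below ``ft_threshold`` (percent).  Missing f/t
    values contribute nothing.
    """
    if len(calls) != len(ft_psa_percent):
        raise ValueError("calls and f/t PSA values must be aligned")
    out = []
    for call, ft in zip(calls, ft_psa_percent):
        psa_pos = ft is not None and not (isinstance(ft, float) and math.isnan(ft)) and ft < ft_threshold
        out.append(bool(call.positive or psa_pos))
    return out
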