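"""Sample quality control: adjacent-bin MAD of log2 copy ratios, depth check.

The noise metric is the scaled median absolute deviation of first
differences of per-bin log2 copy ratios, pooled genome-wide but never taken
across an arm boundary (boundary jumps are structural, not noise).  A sample
whose MAD exceeds the configured threshold (default 0.38) is flagged and
excluded from downstream analysis; low read depth is flagged as a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import NormalizedCoverage, RawBinCounts
from .genome import BinGrid

__all__ = ["QCConfig", "QCReport", "compute_log2_ratios", "adjacent_bin_mad", "qc_sample"]

#: consistency constant making the MAD unbiased for the SD of a normal sample
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class QCConfig:
    mad_threshold: float = 0.38
    min_read_pairs: int = 15_000_000
    epsilon: float = 1e-9
    mad_scale: float = MAD_SCALE

    def __post_init__(self) -> None:
        if self.mad_threshold <= 0:
            raise ValueError("mad_threshold must be positive")
        if self.min_read_pairs < 0:
            raise ValueError("min_read_pairs must be >= 0")


@dataclass
class QCReport:
    """Per-sample QC outcome: exclusion-grade ``flags``, advisory ``warnings``."""

    sample_id: str
    mad_value: float
    read_pairs: int
    flags: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.flags

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "mad_value": self.mad_value,
            "read_pairs": self.read_pairs,
            "flags": list(self.flags),
            "warnings": list(self.warnings),
            "pass": self.passed,
        }


def compute_log2_ratios(
    sample: NormalizedCoverage, panel_mean: np.ndarray, epsilon: float = 1e-9
) -> np.ndarray:
    """r_b = log2((V_b + eps) / (mean_b + eps)) over the sample's usable bins."""
    panel_mean = np.asarray(panel_mean, dtype=float)
    if panel_mean.shape != sample.values.shape:
        raise ValueError(
            f"bin-set mismatch: sample has {sample.values.size} bins, "
            f"panel mean has {panel_mean.size}"
        )
    if (panel_mean <= 0).any():
        raise ValueError("panel mean must be positive on every usable bin")
    return np.log2((sample.values + epsilon) / (panel_mean + epsilon))


def adjacent_bin_mad(
    log2_ratios: np.ndarray,
    grid: BinGrid,
    bin_index: np.ndarray,
    scale: float = MAD_SCALE,
) -> float:
    """Scaled MAD of adjacent-bin log2-ratio differences, pooled genome-wide.

    Differences are taken only between usable bins that are consecutive
    within the same chromosome arm; the pooled differences d yield
    ``scale * median(|d - median(d)|)``.
    """
    r = np.asarray(log2_ratios, dtype=float)
    arm_ids = grid.arm_ids[np.asarray(bin_index, dtype=np.int64)]
    same_arm = arm_ids[1:] == arm_ids[:-1]
    d = np.diff(r)[same_arm]
    if d.size < 2:
        raise ValueError("fewer than 2 adjacent-bin differences available")
    return float(scale * np.median(np.abs(d - np.median(d))))


def qc_sample(
    sample: NormalizedCoverage,
    panel_mean: np.ndarray,
    raw: RawBinCounts,
    grid: BinGrid,
    cfg: QCConfig = QCConfig(),
) -> QCReport:
    """Evaluate one sample against the MAD and depth rules.

    ``high_mad`` is exclusion-grade (MAD strictly above threshold);
    ``low_depth`` is a warning at desk scale and does not fail the sample.
    """
    ratios = compute_log2_ratios(sample, panel_mean, cfg.epsilon)
    mad = adjacent_bin_mad(ratios, grid, sample.bin_index, cfg.mad_scale)
    flags: list[str] = []
    warnings: list[str] = []
    if mad > cfg.mad_threshold:
        flags.append("high_mad")
    if raw.total_read_pairs < cfg.min_read_pairs:
        warnings.append("low_depth")
    return QCReport(
        sample_id=sample.sample_id,
        mad_value=mad,
        read_pairs=raw.total_read_pairs,
        flags=flags,
        warnings=warnings,
    )
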