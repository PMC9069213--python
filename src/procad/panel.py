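"""Control-panel statistics and bin/arm Z-scores.

The central statistic of the workflow:

    Z = (V_sample - mean(V_control)) / sd(V_control)

computed at bin resolution and at chromosome-arm resolution, where V is
depth-normalized coverage and the control panel supplies the mean and the
(n-1)-denominator sample standard deviation per bin / per arm.  Arms with
too few usable bins are dropped from the retained set, which is how the 44
computable autosomal arms reduce to the smaller usable-arm set on real
mappability.

When a panel member is scored, ``leave_one_out=True`` recomputes the panel
statistics without that sample, giving honestly calibrated (t-tailed) null
scores; scoring with self-inclusion deflates a member's own score (bounded
by (n-1)/sqrt(n)) and is what the cohort-evaluation path uses for the
control group — see the diagnostics documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .coverage import NormalizedCoverage
from .genome import BinGrid

__all__ = [
    "ControlPanel",
    "ArmZProfile",
    "CnvCall",
    "CnvCallSet",
    "build_panel",
    "bin_zscores",
    "arm_zscores",
    "summarize_cnv_events",
]


@dataclass
class ControlPanel:
    """Per-bin and per-arm mean/SD across control samples."""

    control_ids: list[str]
    bin_index: np.ndarray  # usable grid bin indices (after zero-SD drops)
    bin_mean: np.ndarray
    bin_sd: np.ndarray
    retained_arms: list[str]
    arm_mean: np.ndarray  # aligned to retained_arms
    arm_sd: np.ndarray
    min_bins_per_arm: int
    # per-control matrices kept for leave-one-out rescoring
    _bin_matrix: np.ndarray = field(repr=False)  # controls x usable bins
    _arm_matrix: np.ndarray = field(repr=False)  # controls x retained arms
    _arm_of_bin: np.ndarray = field(repr=False)  # arm label per usable bin

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)


def _align(sample: NormalizedCoverage, bin_index: np.ndarray) -> np.ndarray:
    """Subset a sample's V onto the panel's usable bins (order-preserving)."""
    if sample.bin_index.shape == bin_index.shape and (sample.bin_index == bin_index).all():
        return sample.values
    pos = {int(b): i for i, b in enumerate(sample.bin_index)}
    try:
        take = np.array([pos[int(b)] for b in bin_index])
    except KeyError as exc:
        raise ValueError(
            f"{sample.sample_id}: sample is missing panel bin {exc.args[0]}"
        ) from None
    return sample.values[take]


def build_panel(
    controls: list[NormalizedCoverage],
    grid: BinGrid,
    min_bins_per_arm: int = 10,
) -> ControlPanel:
    """Build panel statistics from >= 2 controls on identical usable bins.

    Bin statistics are the per-bin sample mean and SD (ddof=1) across
    controls.  Arm-level coverage V_a is the mean of V_b over the arm's
    usable bins per control; arm_mean/arm_sd are then taken across controls.
    Arms with fewer than ``min_bins_per_arm`` usable bins are dropped, as are
    any zero-SD bins or arms (degenerate panels).
    """
    if len(controls) < 2:
        raise ValueError("build_panel needs >= 2 controls")
    ref = controls[0].bin_index
    mat = np.stack([_align(c, ref) for c in controls])  # controls x bins

    bin_mean = mat.mean(axis=0)
    bin_sd = mat.std(axis=0, ddof=1)
    keep = bin_sd > 0
    if not keep.all():
        n_drop = int((~keep).sum())
        import warnings

        warnings.warn(f"dropping {n_drop} zero-SD bins from panel", stacklevel=2)
    if not keep.any():
        raise ValueError("every panel bin has zero SD; controls are degenerate")
    bin_index = ref[keep]
    mat = mat[:, keep]
    bin_mean, bin_sd = bin_mean[keep], bin_sd[keep]

    arm_of_bin = grid.arm_ids[bin_index]
    arms_in_order = list(dict.fromkeys(grid.arm_ids))
    retained, arm_cols = [], []
    for arm in arms_in_order:
        sel = arm_of_bin == arm
        if sel.sum() < min_bins_per_arm:
            continue
        va = mat[:, sel].mean(axis=1)  # per-control arm coverage
        sd = va.std(ddof=1)
        if sd == 0:
            import warnings

            warnings.warn(f"dropping zero-SD arm {arm} from panel", stacklevel=2)
            continue
        retained.append(arm)
        arm_cols.append(va)
    if not retained:
        raise ValueError(f"no arm has >= {min_bins_per_arm} usable bins")
    arm_matrix = np.stack(arm_cols, axis=1)  # controls x arms
    return ControlPanel(
        control_ids=[c.sample_id for c in controls],
        bin_index=bin_index,
        bin_mean=bin_mean,
        bin_sd=bin_sd,
        retained_arms=retained,
        arm_mean=arm_matrix.mean(axis=0),
        arm_sd=arm_matrix.std(axis=0, ddof=1),
        min_bins_per_arm=min_bins_per_arm,
        _bin_matrix=mat,
        _arm_matrix=arm_matrix,
        _arm_of_bin=arm_of_bin,
    )


def _loo_stats(matrix: np.ndarray, drop_row: int) -> tuple[np.ndarray, np.ndarray]:
    sub = np.delete(matrix, drop_row, axis=0)
    return sub.mean(axis=0), sub.std(axis=0, ddof=1)


def _member_row(panel: ControlPanel, sample_id: str) -> int | None:
    try:
        return panel.control_ids.index(sample_id)
    except ValueError:
        return None


def bin_zscores(
    sample: NormalizedCoverage, panel: ControlPanel, leave_one_out: bool = True
) -> np.ndarray:
    """Z_b = (V_b - bin_mean_b) / bin_sd_b over the panel's usable bins.

    If the sample is a panel member and ``leave_one_out`` is set, the panel
    statistics are recomputed without it (requires >= 3 controls).
    """
    v = _align(sample, panel.bin_index)
    row = _member_row(panel, sample.sample_id)
    if leave_one_out and row is not None:
        if panel.n_controls < 3:
            raise ValueError("leave-one-out scoring needs >= 3 controls")
        mean, sd = _loo_stats(panel._bin_matrix, row)
        sd = np.where(sd > 0, sd, np.nan)
        z = (v - mean) / sd
        return np.nan_to_num(z, nan=0.0)
    return (v - panel.bin_mean) / panel.bin_sd


@dataclass
class ArmZProfile:
    """Per-arm Z-scores for one sample over the panel's retained arms."""

    sample_id: str
    arms: list[str]
    z: np.ndarray

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    def as_series(self) -> pd.Series:
        return pd.Series(self.z, index=self.arms, name=self.sample_id)


def arm_zscores(
    sample: NormalizedCoverage,
    panel: ControlPanel,
    mode: Literal["arm-mean", "stouffer"] = "arm-mean",
    leave_one_out: bool = True,
) -> ArmZProfile:
    """Arm-level Z-scores over the panel's retained arms.

    ``"arm-mean"`` (default): V_a = mean of V_b over the arm;
    Z_a = (V_a - arm_mean_a) / arm_sd_a.  ``"stouffer"``: Z_a =
    sum(Z_b) / sqrt(n_bins) from the bin-level scores.
    """
    if mode not in ("arm-mean", "stouffer"):
        raise ValueError(f"unknown mode {mode!r}")
    v = _align(sample, panel.bin_index)
    row = _member_row(panel, sample.sample_id)
    loo = leave_one_out and row is not None
    if loo and panel.n_controls < 3:
        raise ValueError("leave-one-out scoring needs >= 3 controls")

    if mode == "arm-mean":
        va = np.array(
            [v[panel._arm_of_bin == arm].mean() for arm in panel.retained_arms]
        )
        if loo:
            mean, sd = _loo_stats(panel._arm_matrix, row)
            sd = np.where(sd > 0, sd, np.nan)
            z = np.nan_to_num((va - mean) / sd, nan=0.0)
        else:
            z = (va - panel.arm_mean) / panel.arm_sd
    else:
        zb = bin_zscores(sample, panel, leave_one_out=leave_one_out)
        z = np.array(
            [
                zb[panel._arm_of_bin == arm].sum() / np.sqrt((panel._arm_of_bin == arm).sum())
                for arm in panel.retained_arms
            ]
        )
    if not np.isfinite(z).all():
        raise ValueError(f"{sample.sample_id}: non-finite arm Z-score")
    return ArmZProfile(sample_id=sample.sample_id, arms=list(panel.retained_arms), z=z)


@dataclass(frozen=True)
class CnvCall:
    arm: str
    z: float
    direction: str  # "gain" | "loss"


@dataclass
class CnvCallSet:
    """Arm-level CNV events at a |Z| cutoff for one sample."""

    sample_id: str
    cutoff: float
    calls: list[CnvCall]

    @property
    def n_events(self) -> int:
        return len(self.calls)

    @property
    def positive(self) -> bool:
        return self.n_events >= 1


def summarize_cnv_events(profile: ArmZProfile, cutoff: float = 2.5) -> CnvCallSet:
    """Call every arm with |Z| >= cutoff; direction is the sign of Z."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    calls = [
        CnvCall(arm=a, z=float(z), direction="gain" if z > 0 else "loss")
        for a, z in zip(profile.arms, profile.z)
        if abs(z) >= cutoff
    ]
    return CnvCallSet(sample_id=profile.sample_id, cutoff=cutoff, calls=calls)
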