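"""Cohort-level model object tying the pipeline stages together.

``ProcadModel`` holds a cohort of binned read counts plus its sample sheet;
``fit()`` runs masking, depth normalization, MAD quality control, control-
panel construction, arm-level Z-scoring and max-|Z| classification, and
returns a ``ProcadResults`` carrying the Z matrix, QC reports, calls and the
diagnostic evaluation (ROC/AUC with DeLong CI, confusion metrics with
Wilson continuity-corrected intervals, Youden-optimal cutoff).

Panel members (the benign controls) are scored with self-inclusion by
default: a held-out control's score has heavy t tails under a small panel
(n = 9 in the reference cohort) and would generate spurious arm calls, while
self-inclusion bounds a member's own studentized score at (n-1)/sqrt(n) —
the behaviour consistent with the assay's published 100% specificity.
Leave-one-out scoring remains available (``loo_controls=True``) and is the
right choice for null-calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .coverage import BinMask, NormalizedCoverage, RawBinCounts, filter_bins, normalize_sample
from .diagnostics import (
    ConfusionCounts,
    DiagnosisCall,
    DiagnosticMetrics,
    classify_sample,
    combined_test,
    confusion_metrics,
    youden_optimal_cutoff,
)
from .genome import BinGrid
from .panel import ArmZProfile, ControlPanel, arm_zscores, build_panel, summarize_cnv_events
from .qc import QCConfig, QCReport, compute_log2_ratios, qc_sample
from .segment import SegmentationParams, SegmentSet, segment_genome
from .stats import ROCResult, delong_paired_test, roc_and_auc

__all__ = ["ProcadModel", "ProcadResults"]


class ProcadModel:
    """Arm-level aneuploidy diagnostic model for a binned-coverage cohort.

    Parameters
    ----------
    counts
        One :class:`RawBinCounts` per sample, aligned to ``grid``.
    sample_sheet
        DataFrame with at least ``sample_id`` and ``group`` (PCa/BPH/PIN or
        case/control); optional ``ft_percent``.
    grid
        The bin grid the counts live on.
    controls
        Which benign groups form the normalization panel; the reference
        workflow normalizes against BPH only.
    """

    def __init__(
        self,
        counts: Sequence[RawBinCounts],
        sample_sheet: pd.DataFrame,
        grid: BinGrid,
        controls: tuple[str, ...] = ("BPH", "control"),
        bin_filter: dict | None = None,
        qc_config: QCConfig | None = None,
        min_bins_per_arm: int = 10,
        z_mode: Literal["arm-mean", "stouffer"] = "arm-mean",
        loo_controls: bool = False,
    ) -> None:
        ids = [c.sample_id for c in counts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in counts")
        sheet_ids = set(sample_sheet["sample_id"])
        missing = [i for i in ids if i not in sheet_ids]
        if missing:
            raise ValueError(f"samples missing from sheet: {missing[:5]}")
        self.counts = list(counts)
        self.sample_sheet = sample_sheet.set_index("sample_id", drop=False)
        self.grid = grid
        self.control_groups = controls
        self.bin_filter = bin_filter or {}
        self.qc_config = qc_config or QCConfig()
        self.min_bins_per_arm = min_bins_per_arm
        self.z_mode = z_mode
        self.loo_controls = loo_controls

    @classmethod
    def from_tables(
        cls, count_paths: Sequence, sheet_path, grid: BinGrid, **kw
    ) -> "ProcadModel":
        from .coverage import load_bin_counts
        from .io import read_sample_sheet

        counts = [load_bin_counts(p, grid) for p in count_paths]
        return cls(counts, read_sample_sheet(sheet_path), grid, **kw)

    def _group(self, sample_id: str) -> str:
        return str(self.sample_sheet.loc[sample_id, "group"])

    def is_control(self, sample_id: str) -> bool:
        return self._group(sample_id) in self.control_groups

    def fit(self, cutoff: float = 2.5, run_qc: bool = True) -> "ProcadResults":
        control_counts = [c for c in self.counts if self.is_control(c.sample_id)]
        if len(control_counts) < 2:
            raise ValueError(
                f"need >= 2 control samples in groups {self.control_groups}"
            )
        mask = filter_bins(control_counts, **self.bin_filter)
        normalized = {c.sample_id: normalize_sample(c, mask) for c in self.counts}

        panel_all = build_panel(
            [normalized[c.sample_id] for c in control_counts],
            self.grid,
            self.min_bins_per_arm,
        )

        qc_reports: dict[str, QCReport] = {}
        excluded: list[str] = []
        if run_qc:
            for c in self.counts:
                rep = qc_sample(
                    normalized[c.sample_id], panel_all.bin_mean, c, self.grid, self.qc_config
                )
                qc_reports[c.sample_id] = rep
                if not rep.passed:
                    excluded.append(c.sample_id)

        kept = [c for c in self.counts if c.sample_id not in excluded]
        kept_controls = [c for c in kept if self.is_control(c.sample_id)]
        if set(c.sample_id for c in kept_controls) != set(
            c.sample_id for c in control_counts
        ):
            if len(kept_controls) < 2:
                raise ValueError("too many controls failed QC to build a panel")
            panel = build_panel(
                [normalized[c.sample_id] for c in kept_controls],
                self.grid,
                self.min_bins_per_arm,
            )
        else:
            panel = panel_all

        profiles: dict[str, ArmZProfile] = {}
        for c in kept:
            loo = self.loo_controls and self.is_control(c.sample_id)
            profiles[c.sample_id] = arm_zscores(
                normalized[c.sample_id], panel, mode=self.z_mode, leave_one_out=loo
            )
        calls = {sid: classify_sample(p, cutoff) for sid, p in profiles.items()}
        return ProcadResults(
            model=self,
            mask=mask,
            panel=panel,
            normalized=normalized,
            qc_reports=qc_reports,
            excluded=excluded,
            profiles=profiles,
            calls=calls,
            cutoff=cutoff,
        )


@dataclass
class ProcadResults:
    """Fitted cohort results: Z matrix, QC, calls and evaluation methods."""

    model: ProcadModel
    mask: BinMask
    panel: ControlPanel
    normalized: dict[str, NormalizedCoverage]
    qc_reports: dict[str, QCReport]
    excluded: list[str]
    profiles: dict[str, ArmZProfile]
    calls: dict[str, DiagnosisCall]
    cutoff: float
    _z_matrix: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def z_matrix(self) -> pd.DataFrame:
        """Samples x retained-arms arm-level Z-scores."""
        if self._z_matrix is None:
            self._z_matrix = pd.DataFrame(
                {sid: p.as_series() for sid, p in self.profiles.items()}
            ).T.rename_axis("sample_id")
        return self._z_matrix

    @property
    def labels(self) -> pd.Series:
        """True for malignant (PCa/case) samples, benign otherwise."""
        sheet = self.model.sample_sheet
        return pd.Series(
            {
                sid: sheet.loc[sid, "group"] in ("PCa", "case")
                for sid in self.profiles
            },
            name="is_case",
        )

    @property
    def scores(self) -> pd.Series:
        return pd.Series({sid: c.score for sid, c in self.calls.items()}, name="score")

    def calls_frame(self) -> pd.DataFrame:
        rows = []
        for sid, c in self.calls.items():
            events = summarize_cnv_events(self.profiles[sid], self.cutoff)
            rows.append(
                {
                    "sample_id": sid,
                    "group": self.model._group(sid),
                    "score": c.score,
                    "positive": c.positive,
                    "top_arm": c.contributing_arms[0] if c.contributing_arms else "",
                    "n_events": events.n_events,
                    "events": ";".join(
                        f"{e.arm}:{e.direction}:{e.z:.2f}" for e in events.calls
                    ),
                }
            )
        return pd.DataFrame(rows)

    def confusion(self, cutoff: float | None = None, benign_groups=("BPH",)) -> ConfusionCounts:
        """Confusion counts for PCa vs the given benign groups."""
        cut = self.cutoff if cutoff is None else cutoff
        sheet = self.model.sample_sheet
        tn = tp = fn = fp = 0
        for sid, c in self.calls.items():
            grp = str(sheet.loc[sid, "group"])
            pos = c.score >= cut
            if grp in ("PCa", "case"):
                tp, fn = tp + pos, fn + (not pos)
            elif grp in benign_groups or grp == "control":
                tn, fp = tn + (not pos), fp + pos
        return ConfusionCounts(tn=tn, tp=tp, fn=fn, fp=fp)

    def metrics(self, cutoff: float | None = None, benign_groups=("BPH",)) -> DiagnosticMetrics:
        return confusion_metrics(self.confusion(cutoff, benign_groups))

    def roc(self, benign_groups=("BPH",)) -> ROCResult:
        sheet = self.model.sample_sheet
        keep = [
            sid
            for sid in self.calls
            if str(sheet.loc[sid, "group"]) in ("PCa", "case", "control") + tuple(benign_groups)
        ]
        scores = np.array([self.calls[s].score for s in keep])
        labels = np.array([self.labels[s] for s in keep])
        return roc_and_auc(scores, labels)

    def youden_cutoff(self, candidates: Sequence[float] = (2.0, 2.5, 3.0)) -> float:
        return youden_optimal_cutoff([(c, self.confusion(c)) for c in candidates])

    def compare_with_ft_psa(self, benign_groups=("BPH",)) -> tuple[float, float, float]:
        """Paired DeLong test: CNV score vs f/t PSA (low = positive).

        Samples lacking an f/t value are dropped from the comparison.
        """
        sheet = self.model.sample_sheet
        keep = [
            sid
            for sid in self.calls
            if str(sheet.loc[sid, "group"]) in ("PCa", "case", "control") + tuple(benign_groups)
            and np.isfinite(float(sheet.loc[sid].get("ft_percent", np.nan)))
        ]
        if not keep:
            raise ValueError("no samples with f/t PSA values")
        scores = np.array([self.calls[s].score for s in keep])
        ft = np.array([float(sheet.loc[s, "ft_percent"]) for s in keep])
        labels = np.array([self.labels[s] for s in keep])
        return delong_paired_test(scores, ft, labels, low_is_positive_b=True)

    def combined_calls(self, ft_threshold: float = 16.0) -> pd.Series:
        sheet = self.model.sample_sheet
        ids = list(self.calls)
        ft = [
            float(sheet.loc[s].get("ft_percent", np.nan)) if "ft_percent" in sheet.columns else None
            for s in ids
        ]
        out = combined_test([self.calls[s] for s in ids], ft, ft_threshold)
        return pd.Series(out, index=ids, name="combined_positive")

    def segment(
        self, sample_id: str, params: SegmentationParams = SegmentationParams()
    ) -> SegmentSet:
        """CBS segmentation of one sample's log2 copy ratios vs the panel mean."""
        nc = self.normalized[sample_id]
        v = nc.values
        # align panel mean onto the sample's usable bins
        pos = {int(b): i for i, b in enumerate(nc.bin_index)}
        take = np.array([pos[int(b)] for b in self.panel.bin_index])
        ratios = compute_log2_ratios(
            NormalizedCoverage(sample_id, v[take], self.panel.bin_index),
            self.panel.bin_mean,
        )
        return segment_genome(
            ratios, self.model.grid, self.panel.bin_index, sample_id=sample_id, params=params
        )

    def summary(self) -> str:
        """Human-readable evaluation summary."""
        lines = [
            "ProCAD arm-level aneuploidy model",
            "=" * 48,
            f"samples: {len(self.model.counts)} "
            f"(controls in panel: {self.panel.n_controls}; QC-excluded: {len(self.excluded)})",
            f"retained arms: {len(self.panel.retained_arms)} "
            f"(min {self.panel.min_bins_per_arm} bins/arm)",
            f"operating cutoff: |Z| >= {self.cutoff:g}",
        ]
        try:
            m = self.metrics()
            r = self.roc()
            lines += [
                f"sensitivity: {m.sensitivity.percent:.1f}% "
                f"(95% CI {m.sensitivity.percent_ci[0]:.1f}-{m.sensitivity.percent_ci[1]:.1f})",
                f"specificity: {m.specificity.percent:.1f}% "
                f"(95% CI {m.specificity.percent_ci[0]:.1f}-{m.specificity.percent_ci[1]:.1f})",
                f"accuracy:    {m.accuracy.percent:.1f}%   Youden J: {m.youden_j:.3f}",
                f"AUC: {r.auc:.2f} (95% CI {r.auc_ci[0]:.2f}-{r.auc_ci[1]:.2f})",
            ]
        except ValueError:
            lines.append("(single-class cohort: no diagnostic metrics)")
        pos = [sid for sid, c in self.calls.items() if c.positive]
        lines.append(f"positive samples ({len(pos)}): {', '.join(sorted(pos)) or '-'}")
        return "\n".join(lines)
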