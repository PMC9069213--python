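"""Readers and writers for the pipeline's tabular interchange formats.

Formats: Z-matrix TSV (samples x arms), SEG segmentation tables (1-based
inclusive coordinates, community convention), metrics JSON, ROC CSV, QC
report TSV/JSON, and the sample sheet CSV (``sample_id, group, gleason,
psa_total, psa_free, ft_percent``; "–" or empty f/t entries are missing).
Every write/read pair is a round-trip identity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import DiagnosticMetrics
from .qc import QCReport
from .segment import Segment, SegmentSet
from .stats import ROCResult

__all__ = [
    "write_z_matrix",
    "read_z_matrix",
    "write_seg",
    "read_seg",
    "write_metrics_json",
    "write_roc_csv",
    "write_qc_reports",
    "read_sample_sheet",
    "write_sample_sheet",
]


def write_z_matrix(z: pd.DataFrame, path: str | Path) -> None:
    """Samples x arms Z-score matrix as TSV (index column ``sample_id``)."""
    z.to_csv(path, sep="\t", index_label="sample_id", float_format="%.6f")


def read_z_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if df.empty:
        raise ValueError(f"{path}: empty Z matrix")
    return df


_SEG_COLS = ["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def write_seg(segset: SegmentSet, path: str | Path) -> None:
    """SEG output: 1-based inclusive coordinates, 6 fixed tab-separated columns."""
    rows = [
        (segset.sample_id, s.chrom, s.start + 1, s.end, s.n_bins, round(s.seg_mean, 6))
        for s in segset.segments
    ]
    pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> SegmentSet:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SEG_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing SEG columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: empty SEG file")
    sample = str(df["sample"].iloc[0])
    segs = [
        Segment(
            chrom=str(r["chrom"]),
            arm_id="",  # arm identity is not part of the SEG format
            start=int(r["loc.start"]) - 1,
            end=int(r["loc.end"]),
            n_bins=int(r["num.mark"]),
            seg_mean=float(r["seg.mean"]),
        )
        for _, r in df.iterrows()
    ]
    return SegmentSet(sample_id=sample, segments=segs)


def write_metrics_json(
    metrics: dict[str, DiagnosticMetrics] | DiagnosticMetrics, path: str | Path, **extra
) -> None:
    if isinstance(metrics, DiagnosticMetrics):
        payload: dict = metrics.to_dict()
    else:
        payload = {k: m.to_dict() for k, m in metrics.items()}
    payload.update(extra)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(payload, indent=2, default=_default, allow_nan=True))


def write_roc_csv(roc: ROCResult, path: str | Path) -> None:
    df = pd.DataFrame(roc.points, columns=["cutoff", "sensitivity", "fpr"])
    df.to_csv(path, index=False)


def write_qc_reports(reports: list[QCReport], path: str | Path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps([r.to_dict() for r in reports], indent=2))
    else:
        rows = [
            {
                "sample_id": r.sample_id,
                "mad_value": round(r.mad_value, 6),
                "read_pairs": r.read_pairs,
                "flags": ";".join(r.flags) or ".",
                "warnings": ";".join(r.warnings) or ".",
                "pass": r.passed,
            }
            for r in reports
        ]
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)


_SHEET_COLS = ["sample_id", "group", "gleason", "psa_total", "psa_free", "ft_percent"]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet CSV; "–"/"-"/empty f/t and PSA entries parse as missing."""
    df = pd.read_csv(path, dtype={"sample_id": str, "gleason": str})
    missing = [c for c in ("sample_id", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet lacks required columns {missing}")
    for col in ("psa_total", "psa_free", "ft_percent"):
        if col in df.columns:
            df[col] = pd.to_numeric(
                df[col].replace({"–": np.nan, "-": np.nan, "": np.nan}), errors="coerce"
            )
        else:
            df[col] = np.nan
    if "gleason" not in df.columns:
        df["gleason"] = ""
    df["gleason"] = df["gleason"].fillna("")
    bad = ~df["group"].isin(["PCa", "BPH", "PIN", "case", "control"])
    if bad.any():
        raise ValueError(f"{path}: unknown group label {df.loc[bad, 'group'].iloc[0]!r}")
    return df[_SHEET_COLS + [c for c in df.columns if c not in _SHEET_COLS]]


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
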