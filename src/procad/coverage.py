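"""Per-bin read counting, bin masking and depth normalization.

A sample enters the pipeline either as a coordinate-sorted indexed BAM or as
a pre-computed 4-column bin-count table.  Reads are assigned to the bin
containing their *fragment midpoint* (read midpoint for unpaired reads) —
at 200-kb bins this is equivalent in expectation to per-base coverage
averaging and orders of magnitude faster.

Depth normalization divides each bin count by the mean count over usable
autosomal bins, yielding the coverage value V_b with mean 1 by construction;
V is the quantity the control-panel Z-score operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinGrid, _canon_chrom

__all__ = [
    "RawBinCounts",
    "BinMask",
    "NormalizedCoverage",
    "count_reads_in_bins",
    "load_bin_counts",
    "write_bin_counts",
    "filter_bins",
    "normalize_sample",
]


@dataclass
class RawBinCounts:
    """Integer midpoint-assigned read counts aligned to a BinGrid."""

    sample_id: str
    counts: np.ndarray  # int vector, grid order
    total_read_pairs: int
    source: str = "table"  # "bam" | "table"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError(f"{self.sample_id}: negative bin counts")


@dataclass
class BinMask:
    """Boolean usability vector over the grid with per-bin reason codes."""

    usable: np.ndarray  # bool vector, grid order
    reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.usable = np.asarray(self.usable, dtype=bool)

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def to_bed(self, grid: BinGrid, path: str | Path) -> None:
        df = grid.bins[["chrom", "start", "end"]].copy()
        df["status"] = np.where(self.usable, "usable", "masked")
        df["reason"] = [self.reasons.get(i, ".") for i in range(len(df))]
        df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class NormalizedCoverage:
    """Depth-normalized coverage V_b over usable bins (mean 1 by construction)."""

    sample_id: str
    values: np.ndarray  # float vector over usable bins
    bin_index: np.ndarray  # grid bin indices the values refer to

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_index = np.asarray(self.bin_index, dtype=np.int64)
        if self.values.shape != self.bin_index.shape:
            raise ValueError("values and bin_index must be aligned")


def count_reads_in_bins(
    alignment_source: str | Path,
    grid: BinGrid,
    mapq_min: int = 30,
    dedup: bool = True,
    sample_id: str | None = None,
) -> RawBinCounts:
    """Count fragment midpoints per bin from a coordinate-sorted indexed BAM.

    Primary, non-duplicate (when ``dedup``) alignments with MAPQ >=
    ``mapq_min`` are assigned to the bin containing the fragment midpoint
    (template span for proper pairs, read span otherwise).  Chromosome names
    are reconciled with or without the ``chr`` prefix.
    """
    import pysam

    path = Path(alignment_source)
    af = pysam.AlignmentFile(str(path))
    if not af.has_index():
        raise FileNotFoundError(f"{path}: BAM index required (run samtools index)")

    grid_chroms = set(grid.arms.chromosomes)
    name_map: dict[str, str] = {}
    for ref in af.references:
        canon = _canon_chrom(ref)
        if canon in grid_chroms:
            name_map[ref] = canon
    if not name_map:
        raise ValueError(
            f"no chromosomes shared between BAM ({sorted(af.references)[:5]}...) "
            f"and grid ({sorted(grid_chroms)[:5]}...)"
        )

    counts = np.zeros(grid.n_bins, dtype=np.int64)
    total = 0
    # per-chromosome bin lookup: sorted starts for searchsorted assignment
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in grid.bins.groupby("chrom", sort=False):
        by_chrom[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["bin_index"].to_numpy(),
        )

    for ref, canon in name_map.items():
        if canon not in by_chrom:
            continue
        starts, ends, idxs = by_chrom[canon]
        for aln in af.fetch(ref):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if dedup and aln.is_duplicate:
                continue
            if aln.mapping_quality < mapq_min:
                continue
            if aln.is_paired and aln.is_proper_pair:
                if aln.is_read2:
                    continue  # count each fragment once, via read1
                tlen = aln.template_length
                mid = aln.reference_start + abs(tlen) // 2 if tlen != 0 else (
                    (aln.reference_start + aln.reference_end) // 2
                )
            else:
                mid = (aln.reference_start + aln.reference_end) // 2
            j = np.searchsorted(starts, mid, side="right") - 1
            if j >= 0 and mid < ends[j]:
                counts[idxs[j]] += 1
                total += 1
    af.close()
    return RawBinCounts(
        sample_id=sample_id or path.stem, counts=counts, total_read_pairs=total, source="bam"
    )


def write_bin_counts(raw: RawBinCounts, grid: BinGrid, path: str | Path) -> None:
    """Write counts as 4-column bedGraph-style TSV (chrom, start, end, count)."""
    df = grid.bins[["chrom", "start", "end"]].copy()
    df["count"] = raw.counts
    df.to_csv(path, sep="\t", header=False, index=False)


def load_bin_counts(path: str | Path, grid: BinGrid, sample_id: str | None = None) -> RawBinCounts:
    """Read a (chrom, start, end, count) table congruent with ``grid``.

    Rows may be in any order and may use either chromosome naming style;
    missing, duplicate, or mismatched bins raise with the first offending
    coordinate.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "count"],
        dtype={"start": np.int64, "end": np.int64},
    )
    df["chrom"] = df["chrom"].map(_canon_chrom)
    key = pd.MultiIndex.from_frame(df[["chrom", "start", "end"]])
    if key.duplicated().any():
        dup = df.loc[key.duplicated(), ["chrom", "start", "end"]].iloc[0]
        raise ValueError(f"{path}: duplicate bin {dup.chrom}:{dup.start}-{dup.end}")
    grid_key = pd.MultiIndex.from_frame(grid.bins[["chrom", "start", "end"]])
    lookup = pd.Series(df["count"].to_numpy(), index=key)
    try:
        counts = lookup.reindex(grid_key).to_numpy()
    except Exception as exc:  # pragma: no cover - reindex rarely raises
        raise ValueError(f"{path}: bin coordinates incompatible with grid") from exc
    if np.isnan(counts).any():
        i = int(np.flatnonzero(np.isnan(counts))[0])
        b = grid.bins.iloc[i]
        raise ValueError(f"{path}: missing bin {b.chrom}:{b.start}-{b.end}")
    extra = key.difference(grid_key)
    if len(extra):
        raise ValueError(f"{path}: bin {extra[0]} not present in grid")
    counts = counts.astype(np.int64)
    stem = path.stem
    if stem.endswith(".counts"):
        stem = stem[: -len(".counts")]
    return RawBinCounts(
        sample_id=sample_id or stem,
        counts=counts,
        total_read_pairs=int(counts.sum()),
        source="table",
    )


def filter_bins(
    panel_counts: list[RawBinCounts],
    min_median_count: int = 10,
    max_zero_fraction: float = 0.2,
) -> BinMask:
    """Mask bins that are unreliably covered across a panel of samples.

    A bin is masked when its median count across the panel falls below
    ``min_median_count`` ("low_median") or the fraction of panel samples
    with a zero count exceeds ``max_zero_fraction`` ("zero").
    """
    if len(panel_counts) < 2:
        raise ValueError("filter_bins needs >= 2 panel samples")
    mat = np.stack([p.counts for p in panel_counts])  # samples x bins
    med = np.median(mat, axis=0)
    zero_frac = (mat == 0).mean(axis=0)
    usable = np.ones(mat.shape[1], dtype=bool)
    reasons: dict[int, str] = {}
    for i in np.flatnonzero(zero_frac > max_zero_fraction):
        usable[i] = False
        reasons[int(i)] = "zero"
    for i in np.flatnonzero(med < min_median_count):
        if usable[i]:
            usable[i] = False
            reasons[int(i)] = "low_median"
    if not usable.any():
        raise ValueError("all bins masked; panel too shallow for these thresholds")
    return BinMask(usable=usable, reasons=reasons)


def normalize_sample(raw: RawBinCounts, mask: BinMask) -> NormalizedCoverage:
    """Depth-normalize: V_b = count_b / mean(count over usable bins).

    The result is invariant to uniform depth scaling and has mean exactly 1
    over usable bins.
    """
    if raw.counts.shape[0] != mask.usable.shape[0]:
        raise ValueError("counts and mask are on different grids")
    idx = np.flatnonzero(mask.usable)
    sub = raw.counts[idx].astype(float)
    mean = sub.mean()
    if mean == 0:
        raise ValueError(f"{raw.sample_id}: zero usable coverage")
    return NormalizedCoverage(sample_id=raw.sample_id, values=sub / mean, bin_index=idx)
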