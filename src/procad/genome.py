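"""Genome coordinate scaffold: chromosome arms and fixed-width bins.

All coverage statistics in the pipeline live on a :class:`BinGrid` — an
ordered tiling of each autosomal chromosome arm with half-open, fixed-width
bins.  Bins are tiled *per arm* so that no bin straddles a centromere:
arm-level aneuploidy statistics must never mix p- and q-arm signal.

Coordinates are 0-based half-open internally (BED convention).  A builtin
hg19 arm table derived from the UCSC cytoBand centromere (acen) boundaries is
packaged with the library; any user-supplied 4-column table works the same
way.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["ArmTable", "BinGrid", "load_arm_table", "make_bins"]

_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]


def _canon_chrom(name: str) -> str:
    """Normalize chromosome naming to the 'chr1' style."""
    name = str(name).strip()
    return name if name.startswith("chr") else f"chr{name}"


class ArmTableError(ValueError):
    """Raised when an arm definition table violates its invariants."""


@dataclass(frozen=True)
class ChromArm:
    chrom: str
    arm: str  # "p" or "q"
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ArmTable:
    """Ordered chromosome-arm definitions (autosomes, p before q)."""

    entries: tuple[ChromArm, ...]
    assembly_label: str = "custom"

    def __post_init__(self) -> None:
        seen: dict[str, list[ChromArm]] = {}
        for e in self.entries:
            if e.arm not in ("p", "q"):
                raise ArmTableError(f"{e.chrom}: arm must be 'p' or 'q', got {e.arm!r}")
            if e.start >= e.end:
                raise ArmTableError(f"{e.name}: end ({e.end}) must exceed start ({e.start})")
            seen.setdefault(e.chrom, []).append(e)
        for chrom, arms in seen.items():
            if len(arms) > 2:
                raise ArmTableError(f"{chrom}: more than two arms defined")
            if len(arms) == 2:
                p = next((a for a in arms if a.arm == "p"), None)
                q = next((a for a in arms if a.arm == "q"), None)
                if p is None or q is None:
                    raise ArmTableError(f"{chrom}: duplicate arm labels")
                if p.end > q.start:
                    raise ArmTableError(
                        f"{chrom}: p arm [{p.start},{p.end}) overlaps q arm [{q.start},{q.end})"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def arm_names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.chrom not in out:
                out.append(e.chrom)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [e.chrom for e in self.entries],
                "start": [e.start for e in self.entries],
                "end": [e.end for e in self.entries],
                "arm": [e.arm for e in self.entries],
            }
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# arm table ({self.assembly_label}); 0-based half-open\n")
            self.to_frame().to_csv(fh, sep="\t", header=False, index=False)


def load_arm_table(source: str | Path = "hg19") -> ArmTable:
    """Load an arm table from a TSV path or the builtin ``"hg19"`` identifier.

    The table must have >= 4 columns: chrom, start, end, arm ('p'/'q');
    lines starting with '#' are ignored.  Only autosomes (chr1–chr22) are
    retained — the workflow is restricted to the 44 autosomal arms.
    """
    if str(source) == "hg19":
        ref = importlib.resources.files("procad.data").joinpath("hg19_arms.tsv")
        with importlib.resources.as_file(ref) as p:
            return _read_arm_tsv(p, assembly_label="hg19")
    return _read_arm_tsv(Path(source), assembly_label=str(source))


def _read_arm_tsv(path: Path, assembly_label: str) -> ArmTable:
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ArmTableError(f"{path}:{lineno}: expected >=4 columns, got {len(parts)}")
            chrom = _canon_chrom(parts[0])
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ArmTableError(f"{path}:{lineno}: non-integer coordinate") from exc
            arm = parts[3].strip()
            if not chrom[3:].isdigit():
                raise ArmTableError(f"{path}:{lineno}: unknown chromosome {parts[0]!r}")
            if chrom not in _AUTOSOMES:
                continue  # sex chromosomes / others dropped silently
            entries.append(ChromArm(chrom=chrom, arm=arm, start=start, end=end))
    if not entries:
        raise ArmTableError(f"{path}: no autosomal arm rows found")
    entries.sort(key=lambda e: (int(e.chrom[3:]), e.arm))
    return ArmTable(entries=tuple(entries), assembly_label=assembly_label)


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width bin tiling of an :class:`ArmTable`.

    ``bins`` is a DataFrame with columns (chrom, start, end, arm_id,
    bin_index); bins are half-open, exactly ``bin_size`` wide (trailing
    remainders dropped), and each maps to exactly one arm.
    """

    arms: ArmTable
    bin_size: int
    bins: pd.DataFrame = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def arm_ids(self) -> np.ndarray:
        return self.bins["arm_id"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.bins["chrom"].to_numpy()

    def arm_bin_counts(self) -> pd.Series:
        return self.bins.groupby("arm_id", sort=False).size()

    def arm_indices(self) -> dict[str, np.ndarray]:
        """Map arm name -> integer bin indices, in grid order."""
        return {
            arm: idx.to_numpy()
            for arm, idx in self.bins.groupby("arm_id", sort=False).groups.items()
        }

    def to_bed(self, path: str | Path) -> None:
        df = self.bins[["chrom", "start", "end", "arm_id"]]
        df.to_csv(path, sep="\t", header=False, index=False)


def make_bins(arms: ArmTable, bin_size: int = 200_000) -> BinGrid:
    """Tile every arm with half-open bins of exactly ``bin_size`` bases.

    Tiling starts at each arm's start; a trailing remainder shorter than
    ``bin_size`` is dropped, so the bin count per arm is
    floor(arm_length / bin_size).
    """
    if bin_size < 1_000:
        raise ValueError(f"bin_size must be >= 1000, got {bin_size}")
    if len(arms) == 0:
        raise ArmTableError("empty ArmTable")
    rows: list[tuple[str, int, int, str, int]] = []
    idx = 0
    for e in arms.entries:
        n = e.length // bin_size
        for k in range(n):
            s = e.start + k * bin_size
            rows.append((e.chrom, s, s + bin_size, e.name, idx))
            idx += 1
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "arm_id", "bin_index"])
    return BinGrid(arms=arms, bin_size=bin_size, bins=bins)
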