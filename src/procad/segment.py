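"""Circular binary segmentation (CBS) of per-bin log2 copy ratios.

A from-scratch implementation of the classic recursive change-point search:
for a sequence x of bin-level log2 ratios, find the arc (i, j] whose inside
mean differs most from the outside mean on the standardized scale

    T_ij = (mean_in - mean_out) / (s * sqrt(1/k + 1/(n-k))),   k = j - i,

with s the overall SD of x.  Arc significance is assessed by a permutation
test with the add-one estimator p = (1 + #{perm max |T| >= obs}) /
(1 + n_permutations); significant arcs split the sequence (ternary in the
interior, binary at the boundary) and the procedure recurses.

Segmentation is applied independently per chromosome arm, matching the
arm-level resolution of the diagnostic model; no post-hoc segment pruning
("undo splits") is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinGrid

__all__ = [
    "SegmentationParams",
    "Segment",
    "SegmentSet",
    "max_arc_statistic",
    "cbs_segment",
    "segment_genome",
]


@dataclass(frozen=True)
class SegmentationParams:
    alpha: float = 0.01
    n_permutations: int = 1000
    min_width: int = 2
    rng_seed: int = 0
    max_segment_passes: int = 50  # recursion-depth guard

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


def _arc_t_matrix(x: np.ndarray, min_width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized arc statistic for every admissible (i, j), vectorized.

    Returns (T, I, J) as flat arrays in (i asc, j asc) scan order, so the
    first maximum corresponds to the smallest i then smallest j.
    """
    n = x.size
    s = x.std()
    cs = np.concatenate(([0.0], np.cumsum(x)))
    total = cs[-1]
    i_idx, j_idx = np.triu_indices(n + 1, k=min_width)
    k = j_idx - i_idx
    ok = k <= n - min_width
    i_idx, j_idx, k = i_idx[ok], j_idx[ok], k[ok]
    if s == 0:
        return np.zeros(k.size), i_idx, j_idx
    sum_in = cs[j_idx] - cs[i_idx]
    mean_in = sum_in / k
    mean_out = (total - sum_in) / (n - k)
    t = (mean_in - mean_out) / (s * np.sqrt(1.0 / k + 1.0 / (n - k)))
    return t, i_idx, j_idx


def max_arc_statistic(x: np.ndarray, min_width: int = 2) -> tuple[int, int, float]:
    """Return (i, j, t): the arc (i, j] maximizing |T|, ties to smallest i then j.

    Admissible arcs satisfy min_width <= j - i <= n - min_width.  For a
    constant sequence every arc scores 0 and the first admissible arc is
    returned.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 points, got {n}")
    t, i_idx, j_idx = _arc_t_matrix(x, min_width)
    best = int(np.argmax(np.abs(t)))  # first max in (i, j) scan order
    return int(i_idx[best]), int(j_idx[best]), float(t[best])


def _perm_pvalue(
    x: np.ndarray, observed_abs_t: float, params: SegmentationParams, rng: np.random.Generator
) -> float:
    exceed = 0
    for _ in range(params.n_permutations):
        xp = rng.permutation(x)
        t, _, _ = _arc_t_matrix(xp, params.min_width)
        if np.abs(t).max() >= observed_abs_t:
            exceed += 1
    return (1 + exceed) / (1 + params.n_permutations)


def _segment_rng(params: SegmentationParams, offset: int, length: int) -> np.random.Generator:
    # Deterministic per-(segment position, length) stream: the p-value for a
    # given sub-segment does not depend on the recursion path, which makes
    # the breakpoint set monotone in alpha for a fixed seed.
    ss = np.random.SeedSequence(entropy=params.rng_seed, spawn_key=(offset, length))
    return np.random.default_rng(ss)


def cbs_segment(x: np.ndarray, params: SegmentationParams = SegmentationParams()) -> list[int]:
    """Recursive CBS: return sorted interior breakpoint indices of ``x``.

    A breakpoint at index b means a segment boundary between x[b-1] and x[b].
    Sequences shorter than 4 points (or 2*min_width) are left unsplit.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError(f"need at least 4 points, got {x.size}")
    breaks: list[int] = []

    def recurse(lo: int, hi: int, depth: int) -> None:
        n = hi - lo
        if n < max(4, 2 * params.min_width) or depth > params.max_segment_passes:
            return
        seg = x[lo:hi]
        i, j, t = max_arc_statistic(seg, params.min_width)
        if t == 0.0:
            return
        rng = _segment_rng(params, lo, n)
        p = _perm_pvalue(seg, abs(t), params, rng)
        if p > params.alpha:
            return
        cuts = sorted({c for c in (i, j) if 0 < c < n})
        if not cuts:
            return
        for c in cuts:
            breaks.append(lo + c)
        edges = [lo] + [lo + c for c in cuts] + [hi]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(a, b, depth + 1)

    recurse(0, x.size, 0)
    return sorted(breaks)


@dataclass(frozen=True)
class Segment:
    chrom: str
    arm_id: str
    start: int  # 0-based half-open, from first/last bin of the piece
    end: int
    n_bins: int
    seg_mean: float


@dataclass
class SegmentSet:
    """CBS segments for one sample; segments tile the usable bins per arm."""

    sample_id: str
    segments: list[Segment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "n_bins": [s.n_bins for s in self.segments],
                "seg_mean": [s.seg_mean for s in self.segments],
            }
        )


def segment_genome(
    log2_ratios: np.ndarray,
    grid: BinGrid,
    bin_index: np.ndarray,
    sample_id: str = "sample",
    params: SegmentationParams = SegmentationParams(),
    per_chromosome: bool = False,
) -> SegmentSet:
    """Apply CBS independently per arm (or per chromosome) and collect segments.

    Pieces with too few bins to test are emitted as single segments; segment
    coordinates span the first bin start to the last bin end of the piece,
    and seg_mean is the mean log2 ratio over the piece's bins.
    """
    r = np.asarray(log2_ratios, dtype=float)
    bin_index = np.asarray(bin_index, dtype=np.int64)
    if r.shape != bin_index.shape:
        raise ValueError("ratios and bin_index must be aligned")
    bins = grid.bins.iloc[bin_index]
    group_key = bins["chrom"].to_numpy() if per_chromosome else bins["arm_id"].to_numpy()

    segments: list[Segment] = []
    pos = 0
    for key in dict.fromkeys(group_key):
        sel = np.flatnonzero(group_key == key)
        sub = r[sel]
        sub_bins = bins.iloc[sel]
        if sub.size < max(4, 2 * params.min_width):
            breaks: list[int] = []
        else:
            breaks = cbs_segment(sub, params)
        edges = [0] + breaks + [sub.size]
        for a, b in zip(edges[:-1], edges[1:]):
            piece = sub_bins.iloc[a:b]
            segments.append(
                Segment(
                    chrom=str(piece["chrom"].iloc[0]),
                    arm_id=str(piece["arm_id"].iloc[0]),
                    start=int(piece["start"].iloc[0]),
                    end=int(piece["end"].iloc[-1]),
                    n_bins=b - a,
                    seg_mean=float(sub[a:b].mean()),
                )
            )
        pos += sub.size
    return SegmentSet(sample_id=sample_id, segments=segments)
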