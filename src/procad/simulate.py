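"""Synthetic cohorts of binned low-pass WGS counts with known CNV truth.

The generator emulates the statistical structure of urine-cell low-pass WGS
at the level the pipeline consumes — per-bin read counts — without
simulating reads.  Per sample, a read total is drawn, then distributed over
bins by a multinomial whose weights combine

* bin width,
* a shared per-bin multiplicative bias (lognormal; mappability/GC-like
  structure common to all samples),
* an optional smooth GC-like bias wave,
* per-bin gamma noise with variance ``sample_dispersion`` (the Poisson-gamma
  mixture makes marginal counts negative-binomially overdispersed), and
* the sample's copy-state ratio r = (1 - f) + f * copy_state / 2 on arms
  carrying a simulated event at tumor fraction f.

Counts therefore sum exactly to the drawn read total while remaining
overdispersed relative to Poisson.  A truth table records group labels,
events and expected arm ratios; simulated free/total PSA percentages are
drawn from group-specific distributions loosely matched to published
urology cohorts (demo data only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import RawBinCounts
from .genome import ArmTable, BinGrid, ChromArm, make_bins

__all__ = [
    "CnvEvent",
    "SimConfig",
    "TruthTable",
    "toy_arm_table",
    "simulate_cohort",
    "simulate_alignments",
]


def toy_arm_table(
    n_chroms: int = 4, arm_length: int = 10_000_000, assembly_label: str = "toy"
) -> ArmTable:
    """Small symmetric genome for fast tests: n_chroms x (p + q) arms."""
    entries = []
    for c in range(1, n_chroms + 1):
        entries.append(ChromArm(chrom=f"chr{c}", arm="p", start=0, end=arm_length))
        entries.append(ChromArm(chrom=f"chr{c}", arm="q", start=arm_length, end=2 * arm_length))
    return ArmTable(entries=tuple(entries), assembly_label=assembly_label)


@dataclass(frozen=True)
class CnvEvent:
    """One arm-level copy-number event at a given tumor fraction."""

    arm: str
    copy_state: int  # 0, 1 (loss) or 3, 4 (gain); 2 is diploid and disallowed
    tumor_fraction: float

    def __post_init__(self) -> None:
        if self.copy_state not in (0, 1, 3, 4):
            raise ValueError(f"copy_state must be in {{0,1,3,4}}, got {self.copy_state}")
        if not 0 < self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must be in (0, 1]")

    @property
    def expected_ratio(self) -> float:
        """Mixture coverage ratio r = (1 - f) + f * copy_state / 2."""
        return (1 - self.tumor_fraction) + self.tumor_fraction * self.copy_state / 2


@dataclass
class SimConfig:
    rng_seed: int = 0
    n_controls: int = 9
    n_cases: int = 16
    arm_table: ArmTable = field(default_factory=toy_arm_table)
    bin_size: int = 200_000
    mean_read_pairs: int = 15_000_000
    bin_bias_sd: float = 0.1  # lognormal sigma of the shared per-bin bias
    sample_dispersion: float = 0.02  # per-bin gamma variance (NB overdispersion)
    gc_bias_amplitude: float = 0.0
    read_total_cv: float = 0.1  # spread of per-sample read totals
    events: list[list[CnvEvent]] | None = None  # per-case; default: one gain each
    # f/t PSA (%) per group, loosely matched to published cohort summaries
    ft_psa_case: tuple[float, float] = (14.0, 7.0)  # mean, sd
    ft_psa_control: tuple[float, float] = (18.0, 6.0)
    ft_psa_missing_rate: float = 0.2


@dataclass
class TruthTable:
    """Per-sample simulation truth: labels, events, expected arm ratios."""

    samples: pd.DataFrame  # sample_id, group, ft_psa_percent
    events: dict[str, list[CnvEvent]]

    def expected_ratio(self, sample_id: str, arm: str) -> float:
        for ev in self.events.get(sample_id, []):
            if ev.arm == arm:
                return ev.expected_ratio
        return 1.0

    def to_json(self, path: str | Path) -> None:
        import json

        payload = {
            "samples": self.samples.to_dict(orient="records"),
            "events": {
                s: [
                    {
                        "arm": e.arm,
                        "copy_state": e.copy_state,
                        "tumor_fraction": e.tumor_fraction,
                        "expected_ratio": e.expected_ratio,
                    }
                    for e in evs
                ]
                for s, evs in self.events.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _default_events(cfg: SimConfig, rng: np.random.Generator) -> list[list[CnvEvent]]:
    """One single-copy gain per case on a cycling arm at tumor fraction 0.4."""
    arms = [e.name for e in cfg.arm_table.entries]
    return [
        [CnvEvent(arm=arms[i % len(arms)], copy_state=3, tumor_fraction=0.4)]
        for i in range(cfg.n_cases)
    ]


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[list[RawBinCounts], TruthTable, pd.DataFrame, BinGrid]:
    """Draw a full cohort; returns (counts, truth, sample_sheet, grid).

    Controls are labelled BPH and carry no events; cases are labelled PCa
    and carry ``cfg.events`` (default: one single-copy gain each).  The
    seeded generator makes outputs bit-reproducible.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    grid = make_bins(cfg.arm_table, cfg.bin_size)
    n_bins = grid.n_bins
    arm_ids = grid.arm_ids

    shared_bias = (
        rng.lognormal(mean=0.0, sigma=cfg.bin_bias_sd, size=n_bins)
        if cfg.bin_bias_sd > 0
        else np.ones(n_bins)
    )
    if cfg.gc_bias_amplitude > 0:
        wave = 1 + cfg.gc_bias_amplitude * np.sin(np.linspace(0, 8 * np.pi, n_bins))
        shared_bias = shared_bias * wave

    events = cfg.events if cfg.events is not None else _default_events(cfg, rng)
    if len(events) != cfg.n_cases:
        raise ValueError(f"need {cfg.n_cases} per-case event lists, got {len(events)}")
    known_arms = {e.name for e in cfg.arm_table.entries}
    for evs in events:
        for ev in evs:
            if ev.arm not in known_arms:
                raise ValueError(f"event arm {ev.arm!r} absent from grid")

    counts: list[RawBinCounts] = []
    rows = []
    truth_events: dict[str, list[CnvEvent]] = {}
    groups = [("control", None)] * cfg.n_controls + [
        ("case", events[i]) for i in range(cfg.n_cases)
    ]
    for k, (kind, evs) in enumerate(groups):
        sid = f"CTRL{k:03d}" if kind == "control" else f"CASE{k - cfg.n_controls:03d}"
        ratio = np.ones(n_bins)
        if evs:
            for ev in evs:
                ratio[arm_ids == ev.arm] = ev.expected_ratio
        weights = shared_bias * ratio
        if cfg.sample_dispersion > 0:
            shape = 1.0 / cfg.sample_dispersion
            weights = weights * rng.gamma(shape, 1.0 / shape, size=n_bins)
        p = weights / weights.sum()
        total = max(1, int(round(rng.normal(cfg.mean_read_pairs,
                                            cfg.read_total_cv * cfg.mean_read_pairs))))
        c = rng.multinomial(total, p)
        counts.append(
            RawBinCounts(sample_id=sid, counts=c, total_read_pairs=total, source="table")
        )
        mu, sd = cfg.ft_psa_case if kind == "case" else cfg.ft_psa_control
        ft = float(np.clip(rng.normal(mu, sd), 1.0, 60.0))
        if rng.random() < cfg.ft_psa_missing_rate:
            ft = np.nan
        rows.append(
            {
                "sample_id": sid,
                "group": "PCa" if kind == "case" else "BPH",
                "gleason": "",
                "psa_total": float(np.round(rng.lognormal(2.5, 0.8), 2)),
                "psa_free": np.nan,
                "ft_percent": np.round(ft, 2) if np.isfinite(ft) else np.nan,
            }
        )
        truth_events[sid] = list(evs) if evs else []

    sheet = pd.DataFrame(rows)
    truth = TruthTable(
        samples=sheet[["sample_id", "group", "ft_percent"]].rename(
            columns={"ft_percent": "ft_psa_percent"}
        ),
        events=truth_events,
    )
    return counts, truth, sheet, grid


def simulate_alignments(
    counts: RawBinCounts, grid: BinGrid, path: str | Path, read_length: int = 100
) -> Path:
    """Write a sorted, indexed toy BAM whose fragment midpoints reproduce
    ``counts`` exactly under midpoint binning.

    Guarded to <= 100,000 reads (toy genomes only).  Each count unit becomes
    one proper read pair whose fragment midpoint sits at the bin centre.
    """
    import pysam

    total = int(counts.counts.sum())
    if total > 100_000:
        raise ValueError(f"simulate_alignments is for toy genomes (<= 1e5 reads), got {total}")
    path = Path(path)
    chrom_len: dict[str, int] = {}
    for e in grid.arms.entries:
        chrom_len[e.chrom] = max(chrom_len.get(e.chrom, 0), e.end)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_len.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_len)}
    frag = 2 * read_length
    records = []
    for _, b in grid.bins.iterrows():
        n = int(counts.counts[b.bin_index])
        if n == 0:
            continue
        mid = (b.start + b.end) // 2
        start1 = max(0, mid - frag // 2)
        for r in range(n):
            records.append((tid[b.chrom], start1, b.bin_index, r))
    records.sort()
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for t, start1, bidx, r in records:
            for mate in (0, 1):
                a = pysam.AlignedSegment()
                a.query_name = f"{counts.sample_id}_b{bidx}_r{r}"
                a.query_sequence = "A" * read_length
                a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
                a.reference_id = t
                a.mapping_quality = 60
                a.cigarstring = f"{read_length}M"
                a.is_paired = True
                a.is_proper_pair = True
                a.mate_is_reverse = mate == 0
                a.is_reverse = mate == 1
                a.is_read1 = mate == 0
                a.is_read2 = mate == 1
                a.reference_start = start1 if mate == 0 else start1 + frag - read_length
                a.next_reference_id = t
                a.next_reference_start = start1 + frag - read_length if mate == 0 else start1
                a.template_length = frag if mate == 0 else -frag
                out.write(a)
    # records were appended per position but mates interleave; coordinate-sort
    sorted_path = path.with_suffix(".sorted.bam")
    pysam.sort("-o", str(sorted_path), str(path))
    sorted_path.replace(path)
    pysam.index(str(path))
    return path
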