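"""Published reference tables for the ProCAD urine-cell assay.

Two small fixtures transcribed from the assay's published evaluation on a
28-patient prospective cohort (16 prostate adenocarcinoma, 9 BPH, 3 PIN):

* the baseline sample sheet (pathology class, Gleason score, PSA values and
  the free/total PSA percentage, with "–" entries parsed as missing), and
* the diagnostic confusion matrices at the three |Z| cutoffs {2, 2.5, 3}
  and the two f/t PSA thresholds {10%, 16%}.

These are transcribed reference values, packaged so the evaluation battery
can be exercised and checked without any sequencing data.  Some PSA columns
of the source table are internally inconsistent (the printed f/t percentage
does not always equal the ratio of the printed PSA values); they are kept
verbatim.  ">1000" PSA entries are stored as 1000.0.
"""

from __future__ import annotations

import math

import pandas as pd

from .diagnostics import ConfusionCounts

__all__ = [
    "reference_sample_sheet",
    "reference_confusions",
    "is_high_grade",
]

# (sample_id, age, psa1, psa2, ft_percent, group, gleason)
_SHEET = [
    ("0009315", 68, 11.30, 4.97, 21.63, "BPH", ""),
    ("0009901", 60, 9.81, 10.67, 19.82, "BPH", ""),
    ("0009750", 74, 14.17, 10.99, 19.09, "BPH", ""),
    ("SH-CL", 57, 7.96, 7.76, 8.88, "BPH", ""),
    ("0009973", 70, 23.32, 15.20, 15.75, "BPH", ""),
    ("0010268", 65, 14.38, 9.18, 9.52, "BPH", ""),
    ("0009994", 56, 11.39, 8.35, 14.65, "BPH", ""),
    ("0010622", 65, 10.24, 9.26, 13.61, "BPH", ""),
    ("SH-ZRM", 62, 7.70, 6.81, 23.66, "BPH", ""),
    ("0010253", 56, 13.11, 13.88, 21.13, "PIN", ""),
    ("0010244", 69, 7.29, 6.70, 8.74, "PIN", ""),
    ("0010247", 60, 7.11, 5.64, 22.06, "PIN", ""),
    ("0009552", 69, 1000.00, 1000.00, 9.60, "PCa", "3+3"),
    ("0009330", 79, 121.00, 151.00, 12.45, "PCa", "3+3"),
    ("SH-WSG", 70, 7.98, 8.68, 11.11, "PCa", "3+3"),
    ("SH-ZHJ", 73, 8.41, 3.85, 18.72, "PCa", "3+3"),
    ("0009245", 73, 80.57, 76.09, 22.67, "PCa", "3+4"),
    ("0010245", 65, 15.13, 14.60, 8.15, "PCa", "4+3"),
    ("SH-LHY", 74, 7.82, 6.70, 26.27, "PCa", "4+3"),
    ("0009210", 63, 486.00, 343.80, None, "PCa", "3+5"),
    ("0010753", 77, 14.10, 12.64, 23.82, "PCa", "4+4"),
    ("0009675", 74, 13.90, 11.59, 5.65, "PCa", "4+4"),
    ("SH-JBL", 64, 424.60, 555.01, None, "PCa", "4+4"),
    ("SH-ZYX", 73, 33.07, 29.76, 21.57, "PCa", "4+5"),
    ("0009884", 70, 260.50, 236.28, None, "PCa", "4+5"),
    ("0009834", 69, 1000.00, 56.83, None, "PCa", "4+5"),
    ("0009551", 73, 819.00, 602.99, None, "PCa", "4+5"),
    ("0009476", 79, 1000.00, 1000.00, None, "PCa", "5+4"),
]

# confusion tables (tn, tp, fn, fp): CNV score at |Z| cutoffs, f/t PSA thresholds
_CONFUSIONS: dict[str, tuple[int, int, int, int]] = {
    "z>=2": (3, 15, 1, 6),
    "z>=2.5": (9, 13, 3, 0),
    "z>=3": (9, 8, 8, 0),
    "ft<10": (7, 9, 7, 2),
    "ft<16": (4, 11, 5, 5),
}


def reference_sample_sheet() -> pd.DataFrame:
    """Baseline cohort sheet; missing f/t PSA entries are NaN."""
    df = pd.DataFrame(
        _SHEET,
        columns=["sample_id", "age", "psa_total", "psa_free", "ft_percent", "group", "gleason"],
    )
    df["ft_percent"] = df["ft_percent"].astype(float)
    df["high_grade"] = [
        is_high_grade(g) if grp == "PCa" else False
        for g, grp in zip(df["gleason"], df["group"])
    ]
    return df


def is_high_grade(gleason: str) -> bool:
    """High grade: Gleason sum >= 8, or the 4+3 pattern (sum 7 led by 4)."""
    if not gleason:
        return False
    a, b = (int(v) for v in gleason.split("+"))
    return a + b >= 8 or (a, b) == (4, 3)


def reference_confusions(key: str | float | None = None):
    """Confusion matrices keyed by operating rule.

    Keys: ``"z>=2"``, ``"z>=2.5"``, ``"z>=3"`` for the CNV score;
    ``"ft<10"``, ``"ft<16"`` for the f/t PSA rule.  A bare numeric key is
    treated as a |Z| cutoff.  With no key, the full dict is returned.
    """
    if key is None:
        return {k: ConfusionCounts(*v) for k, v in _CONFUSIONS.items()}
    if isinstance(key, (int, float)) and not isinstance(key, bool):
        num = float(key)
        key = f"z>={int(num)}" if num == int(num) else f"z>={num}"
    if key not in _CONFUSIONS:
        raise KeyError(f"unknown fixture key {key!r}; choose from {sorted(_CONFUSIONS)}")
    return ConfusionCounts(*_CONFUSIONS[key])


def z_cutoff_candidates() -> list[tuple[float, ConfusionCounts]]:
    """The three published |Z| operating points as Youden candidates."""
    return [
        (2.0, ConfusionCounts(*_CONFUSIONS["z>=2"])),
        (2.5, ConfusionCounts(*_CONFUSIONS["z>=2.5"])),
        (3.0, ConfusionCounts(*_CONFUSIONS["z>=3"])),
    ]


def cohort_summary() -> dict:
    """Group sizes and the CNV-positivity proportions used for the CIs."""
    df = reference_sample_sheet()
    return {
        "n_total": len(df),
        "n_pca": int((df.group == "PCa").sum()),
        "n_bph": int((df.group == "BPH").sum()),
        "n_pin": int((df.group == "PIN").sum()),
        "n_high_grade": int(df.high_grade.sum()),
        "cnv_positive_pca": (13, 16),
        "cnv_positive_high_grade": (10, 11),
        "cnv_positive_low_grade": (3, 5),
    }


def _sanity() -> None:  # pragma: no cover - import-time guard
    s = cohort_summary()
    assert s["n_pca"] == 16 and s["n_bph"] == 9 and s["n_pin"] == 3
    assert s["n_high_grade"] == 11
    assert not any(math.isnan(v) for v in (0.0,))


_sanity()
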