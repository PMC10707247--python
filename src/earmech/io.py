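"""Fixtures and structured-text I/O.

The six-patient clinical table is embedded as code-level constants so the
fixture cannot drift; a checksum test pins it.  Audiograms travel as CSV with
header ``frequency_hz,air_db_hl,bone_db_hl,ear`` (bone may be empty), loss /
transmission curves as ``frequency_hz,value``.  Every file written by the
package carries ``#``-comment provenance headers (tool version, config hash,
seed) and is byte-reproducible for a fixed config + seed.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .audiology import Audiogram, LossCurve
from .errors import DataError, FormatError

__all__ = [
    "PatientRecord",
    "load_patient_table",
    "summarize_cohort",
    "CohortSummary",
    "read_audiogram_csv",
    "write_audiogram_csv",
    "write_curve_csv",
    "read_curve_csv",
]


@dataclass(frozen=True)
class PatientRecord:
    """One row of the clinical characteristics table."""

    id: int
    category: str  # incus | stapes | adhesion | adhesion_abnormal_EAC
    age: int
    sex: str  # M | F
    pta4_db_hl: float
    ab_gap_db_hl: float
    tympanogram: str  # A | Ad
    diagnosis: str
    surgery: str


_PATIENT_TABLE = (
    PatientRecord(1, "incus", 24, "M", 31.7, 27.5, "Ad",
                  "Incus long process, complete loss", "Tympanoplasty IIIiM"),
    PatientRecord(2, "incus", 47, "M", 43.3, 25.0, "Ad",
                  "Incus long process, incomplete loss", "Tympanoplasty III"),
    PatientRecord(3, "stapes", 9, "F", 23.3, 18.8, "A",
                  "Monopodal stapes", "Tympanoplasty IVi"),
    PatientRecord(4, "stapes", 50, "M", 70.0, 30.0, "A",
                  "Monopodal stapes; adhesion to the petrosus", "Tympanoplasty I"),
    PatientRecord(5, "adhesion", 56, "M", 23.3, 28.8, "A",
                  "Adhesion of the malleus to the tympanic cavity; fixation of stapes",
                  "Tympanoplasty + stapedotomy"),
    PatientRecord(6, "adhesion_abnormal_EAC", 18, "F", 65.0, 60.0, "A",
                  "Narrow EAC; adhesion of malleus and incus", "Tympanoplasty IIIc"),
)


def load_patient_table() -> list[PatientRecord]:
    """The six embedded clinical records."""
    return list(_PATIENT_TABLE)


@dataclass(frozen=True)
class CohortSummary:
    mean_age: float
    sd_age: Optional[float]  # sample (n-1) SD; None for n == 1
    n_male: int
    n_female: int
    mean_pta4: float
    mean_ab_gap: float

    def display(self) -> str:
        sd = "NA" if self.sd_age is None else f"{self.sd_age:.1f}"
        return (
            f"n={self.n_male + self.n_female} (M {self.n_male} / F {self.n_female}); "
            f"age {self.mean_age:.1f} ± {sd} y; "
            f"PTA4 {self.mean_pta4:.1f} dB HL; AB gap {self.mean_ab_gap:.1f} dB"
        )


def summarize_cohort(records: Sequence[PatientRecord]) -> CohortSummary:
    """Mean/SD age, sex counts and audiometric means; SD uses n-1."""
    if not records:
        raise DataError("cohort is empty")
    ages = [r.age for r in records]
    n = len(ages)
    mean_age = sum(ages) / n
    if n > 1:
        sd_age = math.sqrt(sum((a - mean_age) ** 2 for a in ages) / (n - 1))
    else:
        sd_age = None
    return CohortSummary(
        mean_age=mean_age,
        sd_age=sd_age,
        n_male=sum(1 for r in records if r.sex == "M"),
        n_female=sum(1 for r in records if r.sex == "F"),
        mean_pta4=sum(r.pta4_db_hl for r in records) / n,
        mean_ab_gap=sum(r.ab_gap_db_hl for r in records) / n,
    )


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

_AUDIOGRAM_HEADER = ["frequency_hz", "air_db_hl", "bone_db_hl", "ear"]
_CURVE_HEADER = ["frequency_hz", "value"]


def _header_comment(metadata: Optional[dict]) -> str:
    if not metadata:
        return ""
    parts = " ".join(f"{k}={v}" for k, v in metadata.items())
    return f"# earmech {parts}\n"


def read_audiogram_csv(path: Union[str, Path]) -> Audiogram:
    """Read an audiogram from the documented CSV dialect.

    Header must be exactly ``frequency_hz,air_db_hl,bone_db_hl,ear``; rows are
    one per frequency, strictly increasing; ``bone_db_hl`` may be empty.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = [c.strip() for c in lines[0].rstrip("\n").split(",")]
    if header != _AUDIOGRAM_HEADER:
        raise FormatError(
            f"{path}: bad header {lines[0].rstrip()!r}; "
            f"expected {','.join(_AUDIOGRAM_HEADER)!r}"
        )
    frame = pd.read_csv(_io.StringIO("".join(lines)))
    freqs = frame["frequency_hz"].astype(float).tolist()
    for row, (prev, cur) in enumerate(zip(freqs, freqs[1:]), start=2):
        if cur <= prev:
            raise DataError(
                f"{path}: non-increasing frequency {cur} at data row {row + 1}"
            )
    bone = frame["bone_db_hl"]
    has_bone = bone.notna().all() and len(bone) > 0
    ears = frame["ear"].dropna().unique().tolist()
    ear = ears[0] if ears else "right"
    try:
        return Audiogram(
            ear=ear,
            frequencies=freqs,
            air_db_hl=frame["air_db_hl"].astype(float).tolist(),
            bone_db_hl=bone.astype(float).tolist() if has_bone else None,
        )
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_audiogram_csv(
    path: Union[str, Path], audiogram: Audiogram, metadata: Optional[dict] = None
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(metadata))
        fh.write(",".join(_AUDIOGRAM_HEADER) + "\n")
        bone = audiogram.bone_db_hl or [None] * len(audiogram.frequencies)
        for f, a, b in zip(audiogram.frequencies, audiogram.air_db_hl, bone):
            b_str = "" if b is None else repr(float(b))
            fh.write(f"{float(f)!r},{float(a)!r},{b_str},{audiogram.ear}\n")


def write_curve_csv(
    path: Union[str, Path],
    curve: LossCurve,
    metadata: Optional[dict] = None,
) -> None:
    """Write a loss/transmission curve as ``frequency_hz,value`` CSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(metadata))
        fh.write(",".join(_CURVE_HEADER) + "\n")
        for f, v in zip(curve.frequencies, curve.loss_db):
            fh.write(f"{float(f)!r},{float(v)!r}\n")


def read_curve_csv(path: Union[str, Path]) -> LossCurve:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = [c.strip() for c in lines[0].rstrip("\n").split(",")]
    if header != _CURVE_HEADER:
        raise FormatError(
            f"{path}: bad header {lines[0].rstrip()!r}; expected {','.join(_CURVE_HEADER)!r}"
        )
    frame = pd.read_csv(_io.StringIO("".join(lines)))
    return LossCurve(
        frequencies=frame["frequency_hz"].astype(float).tolist(),
        loss_db=frame["value"].astype(float).tolist(),
    )
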