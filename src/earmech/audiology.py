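"""Audiological interpretation of mechanical transmission curves.

The mechanical layer produces the stapes-footplate volume velocity ``V_SF``
per frequency.  Because the sound pressure generated in the cochlea is the
product of the cochlear impedance and ``V_SF``, the level difference between
a normal and a diseased ear is

    loss(f) [dB] = 20 * log10( |V_SF_normal(f)| / |V_SF_diseased(f)| ),

which is compared against the measured air-bone gap (the audiometric
signature of a conductive, middle-ear loss).  Positive values mean loss; the
ratio is invariant to the drive level by linearity of the mechanics.

Slope conventions follow clinical usage: an *up-sloping* audiogram has its
loss concentrated at low frequencies (stiffness-dominated pathology such as
otosclerosis); a *down-sloping* one is worse at high frequencies
(mass/discontinuity-dominated).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import DataError
from .mechanics import TransmissionCurve, transmission_curve
from .model import MiddleEarModel
from .pathology import PathologyScenario, compose_scenario

__all__ = [
    "Audiogram",
    "LossCurve",
    "ComparisonReport",
    "vsf_ratio_db",
    "pta4",
    "ab_gap",
    "classify_slope",
    "compare_curves",
    "rank_scenarios",
    "simulate_loss_curve",
]

SlopeClass = Literal["up_sloping", "down_sloping", "flat", "peaked", "dipped"]


class Audiogram(BaseModel):
    """Measured pure-tone thresholds (dB HL) over audiometric frequencies."""

    ear: Literal["left", "right"] = "right"
    frequencies: list[float]
    air_db_hl: list[float]
    bone_db_hl: Optional[list[float]] = None

    @model_validator(mode="after")
    def _invariants(self) -> "Audiogram":
        f = self.frequencies
        if any(b >= a for a, b in zip(f[1:], f)):
            raise ValueError("frequencies must be strictly increasing")
        if f and not (125.0 <= f[0] and f[-1] <= 8000.0):
            raise ValueError("frequencies must lie within [125, 8000] Hz")
        if len(self.air_db_hl) != len(f):
            raise ValueError("air threshold list length mismatch")
        if self.bone_db_hl is not None and len(self.bone_db_hl) != len(f):
            raise ValueError("bone threshold list length mismatch")
        for t in self.air_db_hl + (self.bone_db_hl or []):
            if not (-10.0 <= t <= 120.0):
                raise ValueError(f"threshold {t} dB HL outside [-10, 120]")
        return self

    def threshold_at(self, freq: float) -> float:
        for f, a in zip(self.frequencies, self.air_db_hl):
            if f == freq:
                return a
        raise DataError(f"audiogram has no threshold at {freq} Hz")


class LossCurve(BaseModel):
    """Per-frequency hearing loss (dB); also used for measured AB-gap curves."""

    frequencies: list[float]
    loss_db: list[float]
    scenario_name: str = ""

    @model_validator(mode="after")
    def _invariants(self) -> "LossCurve":
        if len(self.frequencies) != len(self.loss_db):
            raise ValueError("frequency and loss lists differ in length")
        if any(not math.isfinite(v) for v in self.loss_db):
            raise ValueError("loss values must be finite")
        return self


@dataclass(frozen=True)
class ComparisonReport:
    """Fit metrics of a simulated loss curve against a measured gap curve."""

    rms_db: float
    pearson_r: float
    slope_class_sim: SlopeClass
    slope_class_meas: SlopeClass
    frequencies: tuple[float, ...]
    per_frequency_residual: tuple[float, ...]


def vsf_ratio_db(normal_curve: TransmissionCurve, diseased_curve: TransmissionCurve,
                 scenario_name: str = "") -> LossCurve:
    """Convert a pair of |V_SF| sweeps into a simulated hearing-loss curve.

    ``loss(f) = 20*log10(|V_SF_normal| / |V_SF_diseased|)``; a diseased
    magnitude of exactly zero yields an ``inf`` sentinel with a warning
    (clamped to the representable maximum so downstream invariants hold).
    """
    if tuple(normal_curve.frequencies) != tuple(diseased_curve.frequencies):
        raise DataError("normal and diseased curves are on different frequency grids")
    if any(v <= 0.0 for v in normal_curve.vsf_magnitude):
        raise DataError("normal |V_SF| must be positive at every frequency")
    loss = []
    for vn, vd in zip(normal_curve.vsf_magnitude, diseased_curve.vsf_magnitude):
        if vd == 0.0:
            warnings.warn("zero diseased |V_SF|; reporting +inf sentinel loss")
            loss.append(float("inf"))
        else:
            loss.append(20.0 * math.log10(vn / vd))
    finite = [v if math.isfinite(v) else 1e6 for v in loss]
    return LossCurve(
        frequencies=list(normal_curve.frequencies),
        loss_db=finite,
        scenario_name=scenario_name,
    )


def pta4(audiogram: Audiogram, convention: str = "mean4") -> float:
    """Four-frequency pure-tone average (dB HL).

    ``mean4``: (a500 + a1000 + a2000 + a4000) / 4.
    ``japanese_weighted``: (a500 + 2*a1000 + a2000) / 4.
    """
    if convention == "mean4":
        return sum(audiogram.threshold_at(f) for f in (500.0, 1000.0, 2000.0, 4000.0)) / 4.0
    if convention == "japanese_weighted":
        return (
            audiogram.threshold_at(500.0)
            + 2.0 * audiogram.threshold_at(1000.0)
            + audiogram.threshold_at(2000.0)
        ) / 4.0
    raise DataError(f"unknown PTA4 convention {convention!r}")


def ab_gap(audiogram: Audiogram) -> tuple[LossCurve, float]:
    """Air-bone gap per frequency and its mean (dB); gaps may be negative."""
    if audiogram.bone_db_hl is None:
        raise DataError("audiogram has no bone-conduction thresholds")
    gaps = [a - b for a, b in zip(audiogram.air_db_hl, audiogram.bone_db_hl)]
    curve = LossCurve(
        frequencies=list(audiogram.frequencies), loss_db=gaps, scenario_name="measured_ab_gap"
    )
    return curve, float(np.mean(gaps))


def classify_slope(
    curve: LossCurve,
    slope_threshold_db_per_octave: float = 3.0,
    peak_threshold_db: float = 10.0,
) -> SlopeClass:
    """Classify a loss / AB-gap curve shape.

    A least-squares slope of loss versus log2(frequency) below
    ``-slope_threshold`` is *up_sloping* (loss concentrated at low
    frequencies), above ``+slope_threshold`` *down_sloping*, otherwise
    *flat*.  An interior point deviating more than ``peak_threshold`` dB from
    its neighbours' mean overrides the slope label as *peaked* (above) or
    *dipped* (below).
    """
    if len(curve.frequencies) < 4:
        raise DataError("slope classification needs at least 4 frequencies")
    values = np.asarray(curve.loss_db, dtype=float)
    octaves = np.log2(np.asarray(curve.frequencies, dtype=float))

    deviations = values[1:-1] - 0.5 * (values[:-2] + values[2:])
    idx = int(np.argmax(np.abs(deviations)))
    if abs(deviations[idx]) > peak_threshold_db:
        return "peaked" if deviations[idx] > 0 else "dipped"

    slope = float(np.polyfit(octaves, values, 1)[0])
    if slope <= -slope_threshold_db_per_octave:
        return "up_sloping"
    if slope >= slope_threshold_db_per_octave:
        return "down_sloping"
    return "flat"


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = float(np.std(x)), float(np.std(y))
    if sx == 0.0 and sy == 0.0:
        return 1.0  # two flat curves are perfectly concordant
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def compare_curves(simulated: LossCurve, measured_gap: LossCurve) -> ComparisonReport:
    """Residuals, RMS error, correlation and slope classes on the common grid."""
    common = [f for f in simulated.frequencies if f in set(measured_gap.frequencies)]
    if len(common) < 4:
        raise DataError(
            f"only {len(common)} overlapping frequencies; need at least 4"
        )
    sim = np.array([simulated.loss_db[simulated.frequencies.index(f)] for f in common])
    meas = np.array([measured_gap.loss_db[measured_gap.frequencies.index(f)] for f in common])
    residual = sim - meas
    return ComparisonReport(
        rms_db=float(np.sqrt(np.mean(residual**2))),
        pearson_r=_pearson(sim, meas),
        slope_class_sim=classify_slope(
            LossCurve(frequencies=common, loss_db=sim.tolist())
        ),
        slope_class_meas=classify_slope(
            LossCurve(frequencies=common, loss_db=meas.tolist())
        ),
        frequencies=tuple(common),
        per_frequency_residual=tuple(float(r) for r in residual),
    )


def simulate_loss_curve(
    model: MiddleEarModel,
    scenario: PathologyScenario,
    freqs: Sequence[float] | None = None,
    normal_curve: TransmissionCurve | None = None,
) -> LossCurve:
    """Compose a scenario on ``model`` and return its simulated loss curve."""
    if normal_curve is None:
        normal_curve = transmission_curve(model, freqs)
    diseased = compose_scenario(model, scenario)
    diseased_curve = transmission_curve(diseased, normal_curve.frequencies)
    return vsf_ratio_db(normal_curve, diseased_curve, scenario_name=scenario.name)


def rank_scenarios(
    measured_gap: LossCurve,
    scenarios: Sequence[PathologyScenario],
    model: MiddleEarModel,
) -> list[tuple[PathologyScenario, ComparisonReport]]:
    """Rank scenarios by fit to a measured AB-gap curve (ascending RMS).

    Ties break on higher Pearson correlation, then on catalog order.
    Scenarios that fail to compose are excluded with a warning.
    """
    if not scenarios:
        raise DataError("scenario list is empty")
    normal_curve = transmission_curve(model, measured_gap.frequencies)
    results = []
    for order, scenario in enumerate(scenarios):
        try:
            simulated = simulate_loss_curve(
                model, scenario, normal_curve=normal_curve
            )
        except Exception as exc:
            warnings.warn(f"scenario {scenario.name!r} excluded: {exc}")
            continue
        report = compare_curves(simulated, measured_gap)
        results.append((report.rms_db, -report.pearson_r, order, scenario, report))
    results.sort(key=lambda t: t[:3])
    return [(scenario, report) for *_, scenario, report in results]
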