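"""Resonance calibration of the unprinted model parameters.

The published material constants fix only the Young's moduli; masses,
cross-sections, lengths and the cochlear load are literature defaults.  The
calibration routine adjusts a single global scale on the *suspension*
cross-section areas (ligaments and tendons anchoring the chain to the
temporal-bone wall — never the published moduli, never the chain elements)
until the umbo-probe resonance of the normal model reaches a target inside
the normal physiological window of 800–1200 Hz.  The routine also reports
the two pathological resonance shifts used as calibration constraints: the
severe cord-softening surrogate must resonate at or below ~750 Hz and the
SAL x10 (otosclerosis) surrogate at or above ~1400 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mechanics import resonant_frequency
from .model import MiddleEarModel
from .pathology import apply_cord_replacement, apply_sal_modification

__all__ = ["CalibrationResult", "calibrate_suspension", "resonance_diagnostics"]

#: Elements whose cross-section the calibration may rescale.
SUSPENSION_ELEMENTS = (
    "AML", "SML", "LML", "PML", "tensor_tympani", "PIL", "SIL", "stapedial_tendon",
)


@dataclass(frozen=True)
class CalibrationResult:
    model: MiddleEarModel
    area_scale: float
    normal_resonance_hz: float
    dehiscence_resonance_hz: float
    sal_x10_resonance_hz: float


def _scaled(model: MiddleEarModel, scale: float) -> MiddleEarModel:
    out = model.copy_model()
    for element_id in SUSPENSION_ELEMENTS:
        if out.has_element(element_id):
            element = out.element(element_id)
            element.cross_section_area = element.cross_section_area * scale
    return out


def resonance_diagnostics(model: MiddleEarModel) -> tuple[float, float, float]:
    """(normal, severe-cord, SAL x10) umbo resonances of ``model`` in Hz."""
    normal = resonant_frequency(model, probe="umbo").frequency_hz
    dehiscent = resonant_frequency(
        apply_cord_replacement(model, 1e-5, "Ver2"), probe="umbo"
    ).frequency_hz
    otosclerotic = resonant_frequency(
        apply_sal_modification(model, 10.0), probe="umbo"
    ).frequency_hz
    return normal, dehiscent, otosclerotic


def calibrate_suspension(
    model: MiddleEarModel,
    target_hz: float = 950.0,
    tolerance_hz: float = 5.0,
    scale_bounds: tuple[float, float] = (0.05, 20.0),
    max_iter: int = 60,
) -> CalibrationResult:
    """Bisect a global suspension-area scale to hit ``target_hz`` at the umbo.

    Resonance rises monotonically with suspension stiffness, so bisection on
    the scale converges; the published moduli are untouched throughout.
    """
    lo, hi = scale_bounds

    def resonance(scale: float) -> float:
        return resonant_frequency(_scaled(model, scale), probe="umbo").frequency_hz

    f_lo, f_hi = resonance(lo), resonance(hi)
    if not (f_lo <= target_hz <= f_hi):
        raise ValueError(
            f"target {target_hz} Hz outside achievable range "
            f"[{f_lo:.0f}, {f_hi:.0f}] Hz for scale bounds {scale_bounds}"
        )
    scale = 1.0
    for _ in range(max_iter):
        scale = 0.5 * (lo + hi)
        f_mid = resonance(scale)
        if abs(f_mid - target_hz) <= tolerance_hz:
            break
        if f_mid < target_hz:
            lo = scale
        else:
            hi = scale

    calibrated = _scaled(model, scale)
    normal, dehiscent, otosclerotic = resonance_diagnostics(calibrated)
    return CalibrationResult(
        model=calibrated,
        area_scale=scale,
        normal_resonance_hz=normal,
        dehiscence_resonance_hz=dehiscent,
        sal_x10_resonance_hz=otosclerotic,
    )
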