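"""Material models for middle-ear elastic elements.

Two material behaviours are supported: a plain linear-elastic solid with a
structural (hysteretic) loss factor, and a generalized Maxwell solid whose
storage modulus stiffens with frequency.  The generalized Maxwell model is a
spring of modulus ``e_inf`` in parallel with one or more spring–dashpot arms
``(e_i, tau_i)``; under harmonic strain at angular frequency ``w = 2*pi*f``
each arm contributes

    storage:  e_i * (w*tau_i)**2 / (1 + (w*tau_i)**2)
    loss:     e_i * (w*tau_i)    / (1 + (w*tau_i)**2)

so the complex modulus is ``E*(f) = E'(f) + i E''(f)``.  At zero frequency
every arm relaxes (``E* = e_inf``); as ``f -> inf`` each arm locks and
contributes its full ``e_i`` with vanishing loss.
"""

from __future__ import annotations

import math
from typing import Optional

from pydantic import BaseModel, Field, model_validator

__all__ = ["ViscoelasticSpec", "MaterialSpec", "maxwell_complex_modulus"]


class ViscoelasticSpec(BaseModel):
    """Generalized Maxwell parameters: equilibrium modulus + relaxation arms."""

    e_inf: float = Field(ge=0.0, description="equilibrium (long-time) modulus, Pa")
    branches: list[tuple[float, float]] = Field(
        min_length=1, description="list of (e_i [Pa], tau_i [s]) Maxwell arms"
    )

    @model_validator(mode="after")
    def _check_branches(self) -> "ViscoelasticSpec":
        for i, (e_i, tau_i) in enumerate(self.branches):
            if e_i <= 0.0:
                raise ValueError(f"branch {i}: modulus e_i must be > 0, got {e_i}")
            if tau_i <= 0.0:
                raise ValueError(f"branch {i}: relaxation time tau_i must be > 0, got {tau_i}")
        return self


class MaterialSpec(BaseModel):
    """Elastic material of an element.

    ``young_modulus`` is the in-phase stiffness constant (Pa); ``loss_factor``
    is the dimensionless structural damping ratio applied as ``E*(1 + i*eta)``.
    When ``viscoelastic`` is set, the frequency-dependent complex modulus from
    :func:`maxwell_complex_modulus` replaces ``young_modulus`` entirely.
    """

    name: str
    young_modulus: float = Field(gt=0.0)
    density: float = Field(default=1200.0, gt=0.0)
    loss_factor: float = Field(default=0.0, ge=0.0)
    viscoelastic: Optional[ViscoelasticSpec] = None

    def complex_modulus(self, freq_hz: float) -> complex:
        """Complex modulus at ``freq_hz`` (Pa), including damping."""
        if self.viscoelastic is not None:
            return maxwell_complex_modulus(self.viscoelastic, freq_hz)
        return self.young_modulus * (1.0 + 1j * self.loss_factor)


def maxwell_complex_modulus(spec: ViscoelasticSpec, freq_hz: float) -> complex:
    """Complex modulus of a generalized Maxwell solid at ``freq_hz``.

    Parameters
    ----------
    spec
        Equilibrium modulus and Maxwell arms.
    freq_hz
        Frequency in Hz; must be non-negative.

    Returns
    -------
    complex
        ``E'(f) + i*E''(f)`` in Pa.  The real (storage) part is monotone
        non-decreasing in frequency; the imaginary (loss) part of a single
        arm peaks at ``w*tau = 1`` and vanishes at both frequency extremes.
    """
    if freq_hz < 0.0:
        raise ValueError(f"frequency must be >= 0 Hz, got {freq_hz}")
    omega = 2.0 * math.pi * freq_hz
    storage = spec.e_inf
    loss = 0.0
    for e_i, tau_i in spec.branches:
        wt = omega * tau_i
        denom = 1.0 + wt * wt
        storage += e_i * wt * wt / denom
        loss += e_i * wt / denom
    return complex(storage, loss)
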