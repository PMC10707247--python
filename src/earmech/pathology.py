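"""Ossicular-malformation manipulations of a middle-ear model.

Each clinical malformation class is expressed as a reusable modification of
the element network, acting only on element materials and cross-sections:

* **cord replacement** — the dysplastic incus long process / incudostapedial
  connection replaced by a soft fibrous cord: Young's modulus scaled down
  from the ossicle value (1.2e10 Pa) by 1e-3 .. 1e-5, cross-section reduced
  to 1/4 ("Ver1") or 1/16 ("Ver2") of the normal long-process area;
* **SAL scaling** — stapedial annular ligament stiffened by a positive
  factor (otosclerosis) or set to the bone modulus ("ossified");
* **ligament fixation** — any suspensory ligament (AML/PIL/SIL/SML/LML/PML)
  stiffened x10 (mild) / x100 / x1000 (severe) or ossified;
* **monopodal stapes** — anterior crus removed, posterior crus replaced by a
  cord-like material, optionally viscoelastic (generalized Maxwell);
* **element removal** — generic building block for the above.

Scenarios are ordered lists of modifications.  Applying a scenario never
mutates the input model; a modified deep copy is returned.
"""

from __future__ import annotations

import warnings
from typing import Literal, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError, TopologyError
from .materials import MaterialSpec, ViscoelasticSpec
from .model import MiddleEarModel

__all__ = [
    "OSSICLE_YOUNG_MODULUS",
    "CORD_E_SCALES",
    "AREA_VERSIONS",
    "FIXATION_MULTIPLIERS",
    "LIGAMENTS",
    "DEFAULT_CRUS_VISCOELASTIC",
    "FixationLevel",
    "Modification",
    "PathologyScenario",
    "apply_cord_replacement",
    "apply_sal_modification",
    "apply_ligament_fixation",
    "apply_monopod_stapes",
    "apply_remove_element",
    "compose_scenario",
    "scenario_catalog",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

#: Bone Young's modulus of the ossicles (Pa); also the "ossified" target value.
OSSICLE_YOUNG_MODULUS = 1.2e10

#: Staged cord softening scales (fractions of the ossicle modulus).  The
#: smallest stage, 1e-5, is the floor: a complete (zero-stiffness)
#: discontinuity is outside the method's validity and is not offered.
CORD_E_SCALES = (1e-3, 1e-4, 1e-5)

#: Cord cross-section as a fraction of the normal incus long-process area.
AREA_VERSIONS = {"Ver1": 0.25, "Ver2": 1.0 / 16.0}

FIXATION_MULTIPLIERS = {"x10": 10.0, "x100": 100.0, "x1000": 1000.0}

LIGAMENTS = ("AML", "PIL", "SIL", "SML", "LML", "PML")

#: Default generalized-Maxwell parameters for a fibrotic crus replacement
#: (used when no patient-specific viscoelastic data are available): a soft
#: equilibrium modulus with one relaxation arm that stiffens the cord and
#: dissipates energy toward the top of the audiometric band.
DEFAULT_CRUS_VISCOELASTIC = ViscoelasticSpec(e_inf=1.2e6, branches=[(1.2e8, 2.0e-5)])

FixationLevel = Literal["x10", "x100", "x1000", "ossified"]

_CORD_ELEMENT = "incus_long_process"
_SAL_ELEMENT = "SAL"


def _set_element_material(
    model: MiddleEarModel,
    element_id: str,
    *,
    young_modulus: Optional[float] = None,
    viscoelastic: Optional[ViscoelasticSpec] = None,
    loss_factor: Optional[float] = None,
    tag: str = "mod",
) -> None:
    """Give ``element_id`` its own (modified) copy of its material."""
    element = model.element(element_id)
    base = model.material_of(element)
    new_name = f"{element_id}__{tag}"
    model.materials[new_name] = MaterialSpec(
        name=new_name,
        young_modulus=base.young_modulus if young_modulus is None else young_modulus,
        density=base.density,
        loss_factor=base.loss_factor if loss_factor is None else loss_factor,
        viscoelastic=viscoelastic,
    )
    element.material = new_name


def apply_cord_replacement(
    model: MiddleEarModel,
    e_scale: float,
    area_version: str = "Ver2",
    allow_custom: bool = False,
) -> MiddleEarModel:
    """Replace the incus long process by a soft fibrous cord.

    The cord keeps the long-process topology but carries Young's modulus
    ``1.2e10 * e_scale`` Pa and cross-section ``base * 1/4`` (Ver1) or
    ``base * 1/16`` (Ver2).  Off-enumeration ``e_scale`` values require
    ``allow_custom``.
    """
    if area_version not in AREA_VERSIONS:
        raise ConfigurationError(
            f"unknown area version {area_version!r}; valid: {sorted(AREA_VERSIONS)}"
        )
    if not allow_custom and e_scale not in CORD_E_SCALES:
        raise ConfigurationError(
            f"e_scale {e_scale} not in the staged set {CORD_E_SCALES}; "
            "pass allow_custom=True for off-enumeration values"
        )
    if e_scale <= 0:
        raise ValueError(f"e_scale must be > 0, got {e_scale}")
    out = model.copy_model()
    if not out.has_element(_CORD_ELEMENT):
        raise TopologyError(f"model has no {_CORD_ELEMENT!r} element to replace")
    _set_element_material(
        out, _CORD_ELEMENT, young_modulus=OSSICLE_YOUNG_MODULUS * e_scale, tag="cord"
    )
    element = out.element(_CORD_ELEMENT)
    element.cross_section_area = element.cross_section_area * AREA_VERSIONS[area_version]
    out.is_normal = False
    return out


def apply_sal_modification(
    model: MiddleEarModel, factor: Union[float, Literal["ossified"]]
) -> MiddleEarModel:
    """Stiffen the stapedial annular ligament (otosclerosis surrogate)."""
    out = model.copy_model()
    if not out.has_element(_SAL_ELEMENT):
        raise TopologyError("model has no SAL element")
    base = out.material_of(out.element(_SAL_ELEMENT)).young_modulus
    if factor == "ossified":
        target = OSSICLE_YOUNG_MODULUS
    else:
        factor = float(factor)
        if factor <= 0.0:
            raise ValueError(f"SAL factor must be > 0, got {factor}")
        target = base * factor
    _set_element_material(out, _SAL_ELEMENT, young_modulus=target, tag="sal")
    if factor != 1.0:
        out.is_normal = False
    return out


def apply_ligament_fixation(
    model: MiddleEarModel, ligament: str, level: FixationLevel
) -> MiddleEarModel:
    """Stiffen one suspensory ligament by a staged factor or ossify it."""
    if ligament not in LIGAMENTS:
        raise ConfigurationError(
            f"unknown ligament {ligament!r}; valid names: {list(LIGAMENTS)}"
        )
    if level not in FIXATION_MULTIPLIERS and level != "ossified":
        raise ConfigurationError(
            f"unknown fixation level {level!r}; valid: "
            f"{sorted(FIXATION_MULTIPLIERS) + ['ossified']}"
        )
    out = model.copy_model()
    if not out.has_element(ligament):
        raise TopologyError(f"model has no {ligament!r} element")
    base = out.material_of(out.element(ligament)).young_modulus
    if level == "ossified":
        target = OSSICLE_YOUNG_MODULUS
    else:
        # a fibro-osseous fixation cannot exceed bone stiffness, so staged
        # multipliers are capped at the ossicle modulus; "ossified" is then
        # always the most severe level for every ligament
        target = min(base * FIXATION_MULTIPLIERS[level], OSSICLE_YOUNG_MODULUS)
    _set_element_material(out, ligament, young_modulus=target, tag=f"fix_{level}")
    out.is_normal = False
    return out


def apply_monopod_stapes(
    model: MiddleEarModel,
    crus_spec: Union[float, ViscoelasticSpec] = DEFAULT_CRUS_VISCOELASTIC,
) -> MiddleEarModel:
    """Remove the anterior crus; replace the posterior crus material.

    ``crus_spec`` is either a plain Young's modulus (Pa; the bone value keeps
    the remaining crus rigid) or a :class:`ViscoelasticSpec`, in which case
    the crus modulus becomes frequency dependent through the generalized
    Maxwell model.  Applying twice is idempotent (warning, not an error).
    """
    out = model.copy_model()
    if out.has_element("anterior_crus"):
        out.elements = [e for e in out.elements if e.id != "anterior_crus"]
    else:
        warnings.warn("anterior crus already absent; monopod stapes is idempotent")
    if not out.has_element("posterior_crus"):
        raise TopologyError("model has no posterior_crus element")
    if isinstance(crus_spec, ViscoelasticSpec):
        _set_element_material(
            out,
            "posterior_crus",
            young_modulus=max(crus_spec.e_inf, 1.0),
            viscoelastic=crus_spec,
            tag="monopod",
        )
    else:
        modulus = float(crus_spec)
        if modulus <= 0.0:
            raise ValueError(f"crus modulus must be > 0, got {modulus}")
        _set_element_material(out, "posterior_crus", young_modulus=modulus, tag="monopod")
    out.is_normal = False
    return out


def apply_remove_element(model: MiddleEarModel, element_id: str) -> MiddleEarModel:
    """Remove a named element (connectivity is re-validated)."""
    out = model.copy_model()
    if not out.has_element(element_id):
        raise TopologyError(f"model has no {element_id!r} element")
    out.elements = [e for e in out.elements if e.id != element_id]
    out.is_normal = False
    out._check_connectivity()
    return out


class Modification(BaseModel):
    """One model manipulation; exactly one variant with its parameters."""

    variant: Literal[
        "cord_replacement", "sal_scale", "ligament_fixation", "monopod_stapes", "remove_element"
    ]
    e_scale: Optional[float] = None
    area_version: Optional[str] = None
    factor: Optional[Union[float, Literal["ossified"]]] = None
    ligament: Optional[str] = None
    level: Optional[FixationLevel] = None
    crus_modulus: Optional[float] = None
    crus_viscoelastic: Optional[ViscoelasticSpec] = None
    element_id: Optional[str] = None
    allow_custom: bool = False

    @model_validator(mode="after")
    def _required_parameters(self) -> "Modification":
        required = {
            "cord_replacement": ("e_scale", "area_version"),
            "sal_scale": ("factor",),
            "ligament_fixation": ("ligament", "level"),
            "monopod_stapes": (),
            "remove_element": ("element_id",),
        }[self.variant]
        missing = [f for f in required if getattr(self, f) is None]
        if missing:
            raise ValueError(f"{self.variant} requires parameters {missing}")
        return self

    def apply(self, model: MiddleEarModel) -> MiddleEarModel:
        if self.variant == "cord_replacement":
            return apply_cord_replacement(
                model, self.e_scale, self.area_version, allow_custom=self.allow_custom
            )
        if self.variant == "sal_scale":
            return apply_sal_modification(model, self.factor)
        if self.variant == "ligament_fixation":
            return apply_ligament_fixation(model, self.ligament, self.level)
        if self.variant == "monopod_stapes":
            if self.crus_viscoelastic is not None:
                return apply_monopod_stapes(model, self.crus_viscoelastic)
            if self.crus_modulus is not None:
                return apply_monopod_stapes(model, self.crus_modulus)
            return apply_monopod_stapes(model)
        return apply_remove_element(model, self.element_id)


class PathologyScenario(BaseModel):
    """Named, ordered list of modifications with free-text provenance."""

    name: str
    modifications: list[Modification] = Field(default_factory=list)
    provenance: str = ""


def compose_scenario(model: MiddleEarModel, scenario: PathologyScenario) -> MiddleEarModel:
    """Apply a scenario's modifications in order to a copy of ``model``."""
    out = model.copy_model()
    for i, modification in enumerate(scenario.modifications):
        try:
            out = modification.apply(out)
        except Exception as exc:
            raise ConfigurationError(
                f"scenario {scenario.name!r}: modification {i} "
                f"({modification.variant}) failed: {exc}"
            ) from exc
    return out


def scenario_catalog() -> list[PathologyScenario]:
    """The six patient scenarios plus the single-ligament ossification sweep."""
    mk = Modification
    catalog = [
        PathologyScenario(
            name="patient1",
            provenance="incudostapedial dysplasia: thin cord (Ver2) at 1e-4 with "
            "suspected early otosclerosis (SAL x8)",
            modifications=[
                mk(variant="cord_replacement", e_scale=1e-4, area_version="Ver2"),
                mk(variant="sal_scale", factor=8.0),
            ],
        ),
        PathologyScenario(
            name="patient2",
            provenance="incomplete incus long-process loss: thick cord (Ver1) at 1e-5",
            modifications=[mk(variant="cord_replacement", e_scale=1e-5, area_version="Ver1")],
        ),
        PathologyScenario(
            name="patient3",
            provenance="monopodal stapes, fibrotic posterior crus with viscoelastic "
            "(generalized Maxwell) material",
            modifications=[
                mk(variant="monopod_stapes", crus_viscoelastic=DEFAULT_CRUS_VISCOELASTIC)
            ],
        ),
        PathologyScenario(
            name="patient4",
            provenance="monopodal stapes with rigid remaining crus and ossified SAL",
            modifications=[
                mk(variant="monopod_stapes", crus_modulus=OSSICLE_YOUNG_MODULUS),
                mk(variant="sal_scale", factor="ossified"),
            ],
        ),
        PathologyScenario(
            name="patient5",
            provenance="illustrative: malleus-side adhesion (AML+SML ossified) "
            "combined with SAL stiffening x10",
            modifications=[
                mk(variant="ligament_fixation", ligament="AML", level="ossified"),
                mk(variant="ligament_fixation", ligament="SML", level="ossified"),
                mk(variant="sal_scale", factor=10.0),
            ],
        ),
        PathologyScenario(
            name="patient6",
            provenance="adhesion of malleus and incus: AML, LML, SML, PML, SIL, PIL "
            "fixed (ossified), SAL untouched",
            modifications=[
                mk(variant="ligament_fixation", ligament=lig, level="ossified")
                for lig in ("AML", "LML", "SML", "PML", "SIL", "PIL")
            ],
        ),
    ]
    for lig in ("AML", "PIL", "SIL", "SML"):
        catalog.append(
            PathologyScenario(
                name=f"ossified_{lig}",
                provenance=f"single-ligament ossification sweep: {lig}",
                modifications=[mk(variant="ligament_fixation", ligament=lig, level="ossified")],
            )
        )
    return catalog


# ---------------------------------------------------------------------------
# scenario serialization (same structured-text dialect as model configs)
# ---------------------------------------------------------------------------

def scenario_to_yaml(scenario: PathologyScenario) -> str:
    payload = {
        "scenario": {
            "name": scenario.name,
            "provenance": scenario.provenance,
            "modifications": [
                {k: v for k, v in m.model_dump().items() if v is not None and k != "allow_custom"}
                | ({"allow_custom": True} if m.allow_custom else {})
                for m in scenario.modifications
            ],
        }
    }
    return yaml.safe_dump(payload, sort_keys=False)


def scenario_from_yaml(text: str) -> PathologyScenario:
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "scenario" not in raw:
        raise ConfigurationError("scenario document must contain a 'scenario' block")
    block = raw["scenario"]
    try:
        return PathologyScenario(
            name=block["name"],
            provenance=block.get("provenance", ""),
            modifications=[Modification(**m) for m in block.get("modifications", [])],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid scenario block: {exc}") from exc
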