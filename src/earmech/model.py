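"""Reduced anatomical network of the human middle ear.

The ossicular chain is represented as a small lumped finite-element network:
rigid ossicle inertias at named anatomical nodes, connected to each other and
to the temporal-bone wall by axial elastic elements (ligaments, tendons,
joints, the incus long process and the stapes crura), driven by a tonal
pressure acting on the tympanic-membrane effective area at the umbo, and
terminated by a lumped cochlear load (resistance + compliance) at the stapes
footplate.  Element stiffness is ``E(f) * A / L``; all pathology manipulations
act on the element materials, so the relative effects of stiffening or
softening a named structure are preserved even though the 3-D geometry is
reduced to a piston-axis network.

Node positions are in metres; the shipped configuration lays the chain out
along the x axis with one translational degree of freedom per mobile node.
Wall-anchor nodes carry no degrees of freedom and act as ground.
"""

from __future__ import annotations

import hashlib
from collections import deque
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError, TopologyError
from .materials import MaterialSpec

__all__ = [
    "DOF",
    "NodeSpec",
    "ElasticElement",
    "RigidInertia",
    "CochlearLoad",
    "TympanicDrive",
    "MiddleEarModel",
    "build_normal_model",
    "load_model_config",
    "save_model_config",
    "default_config_path",
    "REQUIRED_COMPONENTS",
]

DOF = Literal["x", "y", "z"]

#: Named structures every normal-ear configuration must contain (unless
#: explicitly disabled): the six suspensory ligaments, the annular ligament,
#: both tendons and both inter-ossicular joints.
REQUIRED_COMPONENTS = (
    "AML",
    "PIL",
    "SIL",
    "SML",
    "LML",
    "PML",
    "SAL",
    "tensor_tympani",
    "stapedial_tendon",
    "incudomalleolar_joint",
    "incudostapedial_joint",
)


class NodeSpec(BaseModel):
    id: str
    position: tuple[float, float, float]
    dofs: tuple[DOF, ...] = ()

    @property
    def fixed(self) -> bool:
        return len(self.dofs) == 0

    @model_validator(mode="after")
    def _finite(self) -> "NodeSpec":
        for p in self.position:
            if not (p == p and abs(p) < float("inf")):
                raise ValueError(f"node {self.id}: position must be finite")
        return self


class ElasticElement(BaseModel):
    """Axial/shear/rotational spring between two nodes.

    Axial stiffness is ``E*A/L``.  Shear elements use the shear modulus
    ``G = E / (2*(1+nu))`` with ``nu = 0.3``; rotational elements are carried
    as an equivalent translational stiffness at the attachment point (the
    reduced network has no rotational degrees of freedom).
    """

    id: str
    kind: Literal["axial", "shear", "rotational"] = "axial"
    node_a: str
    node_b: str
    material: str
    cross_section_area: float = Field(gt=0.0)
    length: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _distinct_nodes(self) -> "ElasticElement":
        if self.node_a == self.node_b:
            raise ValueError(f"element {self.id}: node_a == node_b ({self.node_a})")
        return self

    def stiffness(self, material: MaterialSpec, freq_hz: float) -> complex:
        """Complex scalar stiffness E(f)*A/L at ``freq_hz`` (N/m)."""
        modulus = material.complex_modulus(freq_hz)
        if self.kind == "shear":
            modulus = modulus / (2.0 * (1.0 + 0.3))
        return modulus * self.cross_section_area / self.length


class RigidInertia(BaseModel):
    body: Literal["malleus", "incus", "stapes", "tympanic_membrane_effective"]
    mass: float = Field(gt=0.0, description="kg")
    attached_nodes: tuple[str, ...] = Field(min_length=1)


class CochlearLoad(BaseModel):
    """Lumped cochlear input impedance seen by the stapes footplate."""

    resistance: float = Field(gt=0.0, description="N*s/m")
    compliance: float = Field(gt=0.0, description="m/N")
    footplate_node: str = "footplate"
    footplate_area: float = Field(default=3.2e-6, gt=0.0, description="m^2")


class TympanicDrive(BaseModel):
    effective_area: float = Field(gt=0.0, description="m^2")
    pressure_pa: float = Field(ge=0.0, description="Pa")
    drive_node: str = "umbo"


class MiddleEarModel(BaseModel):
    """Complete element network, assembled and solved per frequency."""

    materials: dict[str, MaterialSpec]
    nodes: list[NodeSpec]
    elements: list[ElasticElement]
    inertias: list[RigidInertia]
    drive: TympanicDrive
    cochlear_load: CochlearLoad
    frequency_grid: list[float] = Field(
        default_factory=lambda: [125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0]
    )
    is_normal: bool = True

    # -- accessors -------------------------------------------------------
    @property
    def umbo_node(self) -> str:
        return self.drive.drive_node

    @property
    def footplate_node(self) -> str:
        return self.cochlear_load.footplate_node

    def node(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise TopologyError(f"node {node_id!r} not in model")

    def element(self, element_id: str) -> ElasticElement:
        for e in self.elements:
            if e.id == element_id:
                return e
        raise TopologyError(f"element {element_id!r} not in model")

    def has_element(self, element_id: str) -> bool:
        return any(e.id == element_id for e in self.elements)

    def material_of(self, element: ElasticElement) -> MaterialSpec:
        try:
            return self.materials[element.material]
        except KeyError:
            raise ConfigurationError(
                f"element {element.id} references unknown material {element.material!r}"
            ) from None

    def copy_model(self) -> "MiddleEarModel":
        return self.model_copy(deep=True)

    # -- validation ------------------------------------------------------
    @model_validator(mode="after")
    def _validate_network(self) -> "MiddleEarModel":
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate node ids: {dup}")
        known = set(ids)
        for e in self.elements:
            for nid in (e.node_a, e.node_b):
                if nid not in known:
                    raise ValueError(f"element {e.id} references unknown node {nid!r}")
            if e.material not in self.materials:
                raise ValueError(f"element {e.id} references unknown material {e.material!r}")
        bodies = [i.body for i in self.inertias]
        if len(set(bodies)) != len(bodies):
            raise ValueError("each rigid body may appear at most once")
        for i in self.inertias:
            for nid in i.attached_nodes:
                if nid not in known:
                    raise ValueError(f"inertia {i.body} attached to unknown node {nid!r}")
        for nid in (self.drive.drive_node, self.cochlear_load.footplate_node):
            if nid not in known:
                raise ValueError(f"model references unknown node {nid!r}")
        for f in self.frequency_grid:
            if not (125.0 <= f <= 8000.0):
                raise ValueError(f"frequency grid value {f} Hz outside [125, 8000]")
        self._check_connectivity()
        return self

    def _check_connectivity(self) -> None:
        """Drive node must reach the footplate; every free node needs support."""
        adj: dict[str, set[str]] = {n.id: set() for n in self.nodes}
        for e in self.elements:
            adj[e.node_a].add(e.node_b)
            adj[e.node_b].add(e.node_a)
        free_unsupported = [
            n.id for n in self.nodes if not n.fixed and not adj[n.id]
        ]
        if free_unsupported:
            raise TopologyError(
                f"free nodes with no attached element (unsupported): {free_unsupported}"
            )
        seen = {self.drive.drive_node}
        queue = deque(seen)
        while queue:
            for nxt in adj[queue.popleft()]:
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        if self.cochlear_load.footplate_node not in seen:
            unreachable = sorted(set(adj) - seen)
            raise TopologyError(
                "drive node cannot reach the footplate; unreachable nodes: "
                f"{unreachable}"
            )


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------

def default_config_path() -> Path:
    """Path of the shipped, calibrated normal-ear configuration."""
    return Path(str(resources.files("earmech").joinpath("data/normal_ear.yaml")))


def _drive_from_config(section: dict) -> TympanicDrive:
    from .mechanics import spl_to_pressure

    section = dict(section)
    level = section.pop("level_db_spl", None)
    if level is not None and "pressure_pa" not in section:
        section["pressure_pa"] = spl_to_pressure(level)
    return TympanicDrive(**section)


def load_model_config(source: Union[str, Path, dict]) -> MiddleEarModel:
    """Load and validate a structured-text model configuration.

    ``source`` may be a YAML path or an already-parsed mapping with sections
    ``materials, nodes, elements, inertias, drive, cochlea, frequency_grid``
    and an optional ``disabled`` list of component names.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigurationError("model configuration must be a mapping")
    missing = [
        s for s in ("materials", "nodes", "elements", "inertias", "drive", "cochlea")
        if s not in raw
    ]
    if missing:
        raise ConfigurationError(f"configuration missing sections: {missing}")

    disabled = set(raw.get("disabled") or ())
    try:
        materials = {
            name: MaterialSpec(name=name, **spec)
            for name, spec in raw["materials"].items()
        }
        elements = [
            ElasticElement(**e) for e in raw["elements"] if e["id"] not in disabled
        ]
        kwargs = dict(
            materials=materials,
            nodes=[NodeSpec(**n) for n in raw["nodes"]],
            elements=elements,
            inertias=[RigidInertia(**i) for i in raw["inertias"]],
            drive=_drive_from_config(raw["drive"]),
            cochlear_load=CochlearLoad(**raw["cochlea"]),
            is_normal=not disabled,
        )
        if raw.get("frequency_grid"):
            kwargs["frequency_grid"] = [float(f) for f in raw["frequency_grid"]]
        return MiddleEarModel(**kwargs)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, TopologyError):
            raise
        raise ConfigurationError(str(exc)) from exc


def build_normal_model(config: Union[str, Path, dict, None] = None) -> MiddleEarModel:
    """Build the normal-ear model from ``config`` (default: shipped calibrated).

    Every required named component (:data:`REQUIRED_COMPONENTS`) must be
    present unless listed under ``disabled`` in the configuration, in which
    case the returned model is flagged ``is_normal=False``.
    """
    raw: dict
    if config is None:
        config = default_config_path()
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(config)
    disabled = set(raw.get("disabled") or ())
    present = {e["id"] for e in raw.get("elements", ())}
    missing = [c for c in REQUIRED_COMPONENTS if c not in present and c not in disabled]
    if missing:
        raise ConfigurationError(
            f"normal-ear configuration is missing required components: {missing}"
        )
    return load_model_config(raw)


def save_model_config(model: MiddleEarModel, path: Union[str, Path]) -> None:
    """Serialize a model back to the YAML configuration dialect."""
    raw = {
        "materials": {
            name: {k: v for k, v in m.model_dump().items() if k != "name" and v is not None}
            for name, m in model.materials.items()
        },
        "nodes": [
            {"id": n.id, "position": list(n.position), "dofs": list(n.dofs)}
            for n in model.nodes
        ],
        "elements": [e.model_dump() for e in model.elements],
        "inertias": [
            {"body": i.body, "mass": i.mass, "attached_nodes": list(i.attached_nodes)}
            for i in model.inertias
        ],
        "drive": model.drive.model_dump(),
        "cochlea": model.cochlear_load.model_dump(),
        "frequency_grid": model.frequency_grid,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def config_hash(source: Union[str, Path]) -> str:
    """Short sha256 of a configuration file, for output provenance headers."""
    data = Path(source).read_bytes()
    return hashlib.sha256(data).hexdigest()[:12]
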