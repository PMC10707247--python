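"""Frequency-domain solution of the middle-ear element network.

For each drive frequency ``f`` the network is assembled into a complex
dynamic-stiffness matrix over the active translational degrees of freedom,

    D(f) = K(f) - (2*pi*f)^2 * M + Z_cochlea(f),

where ``K(f)`` collects element stiffnesses ``E(f)*A/L`` projected on the
element axis (structural damping enters through the complex modulus), ``M``
is the lumped ossicle mass matrix, and the cochlear load adds
``i*omega*R + 1/C`` at the footplate.  Solving ``D u = F`` for the tonal
pressure force at the umbo gives nodal displacements; velocities are
``i*omega*u``.  The stapes-footplate volume velocity ``V_SF`` (velocity times
footplate area) is the transmission output that the audiology layer converts
into hearing-loss curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import SolverError, TopologyError

if TYPE_CHECKING:  # pragma: no cover
    from .model import MiddleEarModel

__all__ = [
    "spl_to_pressure",
    "dof_index",
    "assemble_dynamic_stiffness",
    "harmonic_response",
    "footplate_volume_velocity",
    "transmission_curve",
    "resonant_frequency",
    "NodalResponse",
    "TransmissionCurve",
    "ResonanceResult",
]

_P_REF = 20e-6  # Pa, reference pressure for dB SPL

_DOF_AXIS = {"x": 0, "y": 1, "z": 2}


def spl_to_pressure(level_db_spl: float) -> float:
    """Convert a sound pressure level (dB SPL re 20 uPa) to pascals."""
    if not math.isfinite(level_db_spl):
        raise ValueError("SPL must be finite")
    return _P_REF * 10.0 ** (level_db_spl / 20.0)


def dof_index(model: "MiddleEarModel") -> dict[tuple[str, str], int]:
    """Global index of every active (node, dof) pair, in declaration order."""
    index: dict[tuple[str, str], int] = {}
    for node in model.nodes:
        for dof in node.dofs:
            index[(node.id, dof)] = len(index)
    return index


def _element_direction(model: "MiddleEarModel", element) -> np.ndarray:
    a = np.asarray(model.node(element.node_a).position, dtype=float)
    b = np.asarray(model.node(element.node_b).position, dtype=float)
    d = b - a
    norm = np.linalg.norm(d)
    if norm == 0.0:
        return np.array([1.0, 0.0, 0.0])  # coincident nodes: default piston axis
    return d / norm


def assemble_dynamic_stiffness(model: "MiddleEarModel", freq: float) -> sp.csc_matrix:
    """Assemble the complex dynamic stiffness ``D(f)`` over active dofs.

    The matrix is symmetric (not Hermitian): structural damping and the
    cochlear load enter as complex entries of a symmetric system.
    """
    if freq <= 0.0:
        raise ValueError(f"frequency must be > 0 Hz, got {freq}")
    omega = 2.0 * math.pi * freq
    index = dof_index(model)
    n = len(index)
    mat = sp.lil_matrix((n, n), dtype=complex)

    for element in model.elements:
        k = element.stiffness(model.material_of(element), freq)
        direction = _element_direction(model, element)
        for node_i, sign_i in ((element.node_a, 1.0), (element.node_b, -1.0)):
            for node_j, sign_j in ((element.node_a, 1.0), (element.node_b, -1.0)):
                for dof_i in model.node(node_i).dofs:
                    ii = index.get((node_i, dof_i))
                    for dof_j in model.node(node_j).dofs:
                        jj = index.get((node_j, dof_j))
                        proj = direction[_DOF_AXIS[dof_i]] * direction[_DOF_AXIS[dof_j]]
                        mat[ii, jj] += sign_i * sign_j * k * proj

    for inertia in model.inertias:
        share = inertia.mass / len(inertia.attached_nodes)
        for node_id in inertia.attached_nodes:
            for dof in model.node(node_id).dofs:
                ii = index[(node_id, dof)]
                mat[ii, ii] += -(omega**2) * share

    load = model.cochlear_load
    z = 1j * omega * load.resistance + 1.0 / load.compliance
    for dof in model.node(load.footplate_node).dofs:
        ii = index[(load.footplate_node, dof)]
        mat[ii, ii] += z

    return mat.tocsc()


@dataclass(frozen=True)
class NodalResponse:
    """Complex nodal velocities of one harmonic solve."""

    freq_hz: float
    velocities: dict[tuple[str, str], complex]

    def velocity(self, node_id: str, dof: str = "x") -> complex:
        try:
            return self.velocities[(node_id, dof)]
        except KeyError:
            raise TopologyError(f"no active dof ({node_id!r}, {dof!r}) in response") from None


def harmonic_response(
    model: "MiddleEarModel", freq: float, pressure_pa: float | None = None
) -> NodalResponse:
    """Solve the harmonic response at ``freq`` for the tonal tympanic drive.

    ``pressure_pa`` overrides the model's drive pressure (default 80 dB SPL in
    the shipped configuration).  Velocities scale linearly with pressure.
    """
    if not (0.0 < freq <= 20000.0):
        raise ValueError(f"frequency {freq} Hz outside (0, 20000]")
    omega = 2.0 * math.pi * freq
    pressure = model.drive.pressure_pa if pressure_pa is None else pressure_pa
    index = dof_index(model)
    matrix = assemble_dynamic_stiffness(model, freq)

    force = np.zeros(len(index), dtype=complex)
    drive_dofs = model.node(model.drive.drive_node).dofs
    if not drive_dofs:
        raise TopologyError(f"drive node {model.drive.drive_node!r} has no active dof")
    force[index[(model.drive.drive_node, drive_dofs[0])]] = pressure * model.drive.effective_area

    try:
        disp = spla.spsolve(matrix, force)
    except Exception as exc:  # pragma: no cover - defensive
        raise SolverError(f"solve failed at {freq} Hz: {exc}") from exc
    if not np.all(np.isfinite(disp)):
        cond = np.linalg.cond(matrix.toarray())
        raise SolverError(f"singular system at {freq} Hz (condition estimate {cond:.3e})")

    vel = 1j * omega * np.atleast_1d(disp)
    return NodalResponse(freq_hz=freq, velocities={key: complex(vel[i]) for key, i in index.items()})


def footplate_volume_velocity(model: "MiddleEarModel", response: NodalResponse) -> complex:
    """Stapes-footplate volume velocity ``V_SF`` (m^3/s): velocity x area."""
    node = model.cochlear_load.footplate_node
    model.node(node)  # raises TopologyError if absent
    dofs = model.node(node).dofs
    if not dofs:
        raise TopologyError(f"footplate node {node!r} has no active dof")
    return response.velocity(node, dofs[0]) * model.cochlear_load.footplate_area


@dataclass(frozen=True)
class TransmissionCurve:
    """|V_SF| versus frequency for one model (ordered by frequency)."""

    frequencies: tuple[float, ...]
    vsf_magnitude: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.frequencies) != len(self.vsf_magnitude):
            raise ValueError("frequency and magnitude lists differ in length")


def transmission_curve(
    model: "MiddleEarModel", freqs: Sequence[float] | None = None
) -> TransmissionCurve:
    """Sweep ``|V_SF|`` over ``freqs`` (default: the model's frequency grid)."""
    if freqs is None:
        freqs = model.frequency_grid
    freqs = sorted(float(f) for f in freqs)
    if not freqs:
        raise ValueError("frequency list is empty")
    values = []
    for f in freqs:
        try:
            response = harmonic_response(model, f)
            values.append(abs(footplate_volume_velocity(model, response)))
        except SolverError as exc:
            raise SolverError(f"at {f} Hz: {exc}") from exc
    return TransmissionCurve(frequencies=tuple(freqs), vsf_magnitude=tuple(values))


@dataclass(frozen=True)
class ResonanceResult:
    """Location of the probe-velocity peak per unit drive pressure."""

    frequency_hz: float
    peak_velocity_per_pa: float
    no_resonance: bool = False


def _probe_metric(model: "MiddleEarModel", node: str, freq: float) -> float:
    response = harmonic_response(model, freq)
    dof = model.node(node).dofs[0]
    return abs(response.velocity(node, dof)) / model.drive.pressure_pa


def resonant_frequency(
    model: "MiddleEarModel",
    probe: str = "umbo",
    search_range: tuple[float, float] = (200.0, 4000.0),
    grid_points: int = 512,
) -> ResonanceResult:
    """Frequency of maximal probe velocity magnitude per unit drive pressure.

    A log-spaced grid over ``search_range`` locates the coarse maximum; a
    golden-section refinement narrows it to better than +/-1 Hz, with ties
    broken toward the lower frequency.  A maximum sitting on the range
    boundary (monotone response, no interior peak) is returned flagged
    ``no_resonance`` rather than raising.
    """
    lo, hi = search_range
    if not (0.0 < lo < hi <= 20000.0):
        raise ValueError(f"invalid search range {search_range}")
    probe_node = {"umbo": model.umbo_node, "footplate": model.footplate_node}.get(probe, probe)
    model.node(probe_node)

    grid = np.geomspace(lo, hi, grid_points)
    metric = np.array([_probe_metric(model, probe_node, f) for f in grid])
    imax = int(np.argmax(metric))  # first (lowest-frequency) maximum on ties
    if imax == 0 or imax == len(grid) - 1:
        return ResonanceResult(
            frequency_hz=float(grid[imax]),
            peak_velocity_per_pa=float(metric[imax]),
            no_resonance=True,
        )

    a, b = float(grid[imax - 1]), float(grid[imax + 1])
    inv_phi = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - inv_phi * (b - a)
    d = a + inv_phi * (b - a)
    fc = _probe_metric(model, probe_node, c)
    fd = _probe_metric(model, probe_node, d)
    tol = min(0.5, 1e-3 * a)  # +/-1 Hz at audiometric peaks, relative below
    while b - a > tol:
        if fc >= fd:  # ties keep the lower-frequency bracket
            b, d, fd = d, c, fc
            c = b - inv_phi * (b - a)
            fc = _probe_metric(model, probe_node, c)
        else:
            a, c, fc = c, d, fd
            d = a + inv_phi * (b - a)
            fd = _probe_metric(model, probe_node, d)
    best = 0.5 * (a + b)
    return ResonanceResult(
        frequency_hz=float(best),
        peak_velocity_per_pa=float(_probe_metric(model, probe_node, best)),
    )
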