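"""Independent brute-force oracles, written without using the package's
assembly/solve path: a dense matrix is built directly from the model data by
straightforward loops and solved with ``numpy.linalg.solve``."""

import numpy as np

_AXIS = {"x": 0, "y": 1, "z": 2}


def dense_velocities(model, freq, pressure=None):
    """Dense brute-force harmonic solve; returns {(node, dof): velocity}."""
    omega = 2.0 * np.pi * freq
    keys = [(n.id, d) for n in model.nodes for d in n.dofs]
    pos = {n.id: np.asarray(n.position, float) for n in model.nodes}
    n = len(keys)
    D = np.zeros((n, n), dtype=complex)

    for e in model.elements:
        mat = model.materials[e.material]
        if mat.viscoelastic is not None:
            spec = mat.viscoelastic
            wt = [omega * tau for _, tau in spec.branches]
            E = spec.e_inf + sum(
                ei * w * w / (1 + w * w) + 1j * ei * w / (1 + w * w)
                for (ei, _), w in zip(spec.branches, wt)
            )
        else:
            E = mat.young_modulus * (1 + 1j * mat.loss_factor)
        if e.kind == "shear":
            E = E / 2.6
        k = E * e.cross_section_area / e.length
        d = pos[e.node_b] - pos[e.node_a]
        nrm = np.linalg.norm(d)
        u = d / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        for (na, sa) in ((e.node_a, 1.0), (e.node_b, -1.0)):
            for (nb, sb) in ((e.node_a, 1.0), (e.node_b, -1.0)):
                for ka, key_a in enumerate(keys):
                    if key_a[0] != na:
                        continue
                    for kb, key_b in enumerate(keys):
                        if key_b[0] != nb:
                            continue
                        D[ka, kb] += sa * sb * k * u[_AXIS[key_a[1]]] * u[_AXIS[key_b[1]]]

    for inertia in model.inertias:
        share = inertia.mass / len(inertia.attached_nodes)
        for node_id in inertia.attached_nodes:
            for i, key in enumerate(keys):
                if key[0] == node_id:
                    D[i, i] -= omega**2 * share

    load = model.cochlear_load
    for i, key in enumerate(keys):
        if key[0] == load.footplate_node:
            D[i, i] += 1j * omega * load.resistance + 1.0 / load.compliance

    F = np.zeros(n, dtype=complex)
    p = model.drive.pressure_pa if pressure is None else pressure
    drive_key = (model.drive.drive_node, model.node(model.drive.drive_node).dofs[0])
    F[keys.index(drive_key)] = p * model.drive.effective_area

    vel = 1j * omega * np.linalg.solve(D, F)
    return {key: vel[i] for i, key in enumerate(keys)}


def sdof_velocity(freq, k, m, c=0.0, loss_factor=0.0, force=1.0,
                  extra_stiffness=0.0):
    """Closed-form velocity of a driven damped single oscillator."""
    omega = 2.0 * np.pi * freq
    denom = k * (1 + 1j * loss_factor) + extra_stiffness - omega**2 * m + 1j * omega * c
    return 1j * omega * force / denom
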