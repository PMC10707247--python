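# Calibrated normal middle-ear configuration (frozen).
#
# Young's moduli of the ossicles, SAL, AML, PIL, SIL and SML are the standard
# published constants for the human middle ear.  LML and PML are not separately
# characterized and default to the SML value (same anatomical class).  Joint
# (IMJ/ISJ) and tendon moduli are literature-informed defaults: the
# incudostapedial coupling is kept stiff relative to the annular ligament so
# that stapes-side stiffening is felt at the umbo.  Masses, cross-sections,
# lengths and the cochlear load are not uniquely determined by a reduced
# network and were calibrated (see docs/methods.md) so that the umbo-velocity
# resonance of this configuration sits inside the normal physiological window
# of 800-1200 Hz.  Calibration only ever touches these unprinted parameters,
# never the published moduli.
materials:
  ossicle:            {young_modulus: 1.2e+10, density: 2200.0, loss_factor: 0.05}
  aml:                {young_modulus: 2.1e+7,  density: 1200.0, loss_factor: 0.05}
  pil:                {young_modulus: 6.5e+5,  density: 1200.0, loss_factor: 0.05}
  sil:                {young_modulus: 4.9e+6,  density: 1200.0, loss_factor: 0.05}
  sml:                {young_modulus: 4.9e+6,  density: 1200.0, loss_factor: 0.05}
  lml:                {young_modulus: 4.9e+6,  density: 1200.0, loss_factor: 0.05}
  pml:                {young_modulus: 4.9e+6,  density: 1200.0, loss_factor: 0.05}
  sal:                {young_modulus: 6.5e+4,  density: 1200.0, loss_factor: 0.10}
  tendon:             {young_modulus: 2.6e+6,  density: 1200.0, loss_factor: 0.05}
  imj_cartilage:      {young_modulus: 6.0e+6,  density: 1200.0, loss_factor: 0.05}
  isj_coupling:       {young_modulus: 1.2e+8,  density: 1200.0, loss_factor: 0.05}

nodes:
  - {id: umbo,         position: [0.0,    0.0, 0.0], dofs: [x]}
  - {id: incus_body,   position: [0.002,  0.0, 0.0], dofs: [x]}
  - {id: lenticular,   position: [0.004,  0.0, 0.0], dofs: [x]}
  - {id: stapes_head,  position: [0.0043, 0.0, 0.0], dofs: [x]}
  - {id: footplate,    position: [0.0073, 0.0, 0.0], dofs: [x]}
  # temporal-bone wall anchors (ground)
  - {id: wall_aml,     position: [-0.003,  0.0, 0.0], dofs: []}
  - {id: wall_sml,     position: [-0.002,  0.0, 0.0], dofs: []}
  - {id: wall_lml,     position: [-0.0022, 0.0, 0.0], dofs: []}
  - {id: wall_pml,     position: [-0.0024, 0.0, 0.0], dofs: []}
  - {id: wall_tt,      position: [-0.0026, 0.0, 0.0], dofs: []}
  - {id: wall_pil,     position: [0.001,   0.0, 0.0], dofs: []}
  - {id: wall_sil,     position: [0.0005,  0.0, 0.0], dofs: []}
  - {id: wall_st,      position: [0.0063,  0.0, 0.0], dofs: []}
  - {id: oval_window,  position: [0.0074,  0.0, 0.0], dofs: []}

elements:
  # suspensory ligaments and tendons (to the temporal-bone wall)
  - {id: AML,  kind: axial, node_a: umbo,       node_b: wall_aml, material: aml,    cross_section_area: 5.7e-8, length: 3.0e-3}
  - {id: SML,  kind: axial, node_a: umbo,       node_b: wall_sml, material: sml,    cross_section_area: 5.3e-8, length: 2.0e-3}
  - {id: LML,  kind: axial, node_a: umbo,       node_b: wall_lml, material: lml,    cross_section_area: 3.3e-8, length: 2.0e-3}
  - {id: PML,  kind: axial, node_a: umbo,       node_b: wall_pml, material: pml,    cross_section_area: 3.3e-8, length: 2.0e-3}
  - {id: tensor_tympani, kind: axial, node_a: umbo, node_b: wall_tt, material: tendon, cross_section_area: 5.4e-8, length: 2.0e-3}
  - {id: PIL,  kind: axial, node_a: incus_body, node_b: wall_pil, material: pil,    cross_section_area: 2.6e-7, length: 1.0e-3}
  - {id: SIL,  kind: axial, node_a: incus_body, node_b: wall_sil, material: sil,    cross_section_area: 3.3e-8, length: 2.0e-3}
  - {id: stapedial_tendon, kind: axial, node_a: stapes_head, node_b: wall_st, material: tendon, cross_section_area: 3.8e-8, length: 2.0e-3}
  # ossicular chain
  - {id: incudomalleolar_joint,  kind: axial, node_a: umbo,        node_b: incus_body,  material: imj_cartilage, cross_section_area: 1.0e-6, length: 3.0e-5}
  - {id: incus_long_process,     kind: axial, node_a: incus_body,  node_b: lenticular,  material: ossicle,       cross_section_area: 6.0e-7, length: 2.0e-3}
  - {id: incudostapedial_joint,  kind: axial, node_a: lenticular,  node_b: stapes_head, material: isj_coupling,  cross_section_area: 6.0e-7, length: 3.0e-4}
  - {id: anterior_crus,          kind: axial, node_a: stapes_head, node_b: footplate,   material: ossicle,       cross_section_area: 3.0e-7, length: 3.0e-3}
  - {id: posterior_crus,         kind: axial, node_a: stapes_head, node_b: footplate,   material: ossicle,       cross_section_area: 3.0e-7, length: 3.0e-3}
  # stapedial annular ligament (footplate seating in the oval window)
  - {id: SAL,  kind: axial, node_a: footplate, node_b: oval_window, material: sal, cross_section_area: 1.6e-6, length: 1.0e-4}

inertias:
  - {body: tympanic_membrane_effective, mass: 1.0e-5, attached_nodes: [umbo]}
  - {body: malleus, mass: 2.5e-5, attached_nodes: [umbo]}
  - {body: incus,   mass: 2.8e-5, attached_nodes: [incus_body]}
  - {body: stapes,  mass: 3.0e-6, attached_nodes: [stapes_head, footplate]}

drive:
  effective_area: 5.5e-5      # tympanic-membrane effective area, m^2
  level_db_spl: 80.0          # pure-tone drive level (SPL re 20 uPa)
  drive_node: umbo

cochlea:
  resistance: 0.2             # N*s/m, lumped cochlear input resistance
  compliance: 1.0e-2          # m/N, round-window / cochlear compliance
  footplate_node: footplate
  footplate_area: 3.2e-6      # m^2

frequency_grid: [125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0]
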