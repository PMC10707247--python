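# Methods

## Model

The middle ear is represented as a reduced anatomical network rather than a
3-D mesh: five mobile nodes on the piston axis (umbo, incus body, lenticular
process, stapes head, footplate), wall-anchor ground nodes, and axial
elastic elements for every named structure of the sound-conduction chain —
the six suspensory ligaments (AML, SML, LML, PML, PIL, SIL), tensor tympani
and stapedial tendons, incudomalleolar and incudostapedial joints, the incus
long process, both stapes crura and the stapedial annular ligament (SAL).
Ossicle masses are lumped rigid inertias; the tympanic membrane contributes
an effective driving area and an effective mass at the umbo. The cochlea is
a lumped resistance-plus-compliance load at the footplate. Assembly and
harmonic solution follow standard finite-element methodology
(`D(f) = K(f) − ω²M + Z_cochlea`, complex symmetric, solved per frequency);
the network is deliberately one translational degree of freedom per node,
which preserves every stiffness-scaling pathology exactly while discarding
3-D mode shapes.

Assumptions: linear time-invariant mechanics (the dB loss ratio is therefore
drive-level invariant — verified in tests at 60/80/100 dB SPL); harmonic
steady state only; no external-auditory-canal or inner-ear modelling beyond
the lumped load; the 80 dB drive tone is interpreted as dB SPL re 20 µPa at
the tympanic membrane (the loss ratio makes the choice immaterial).

## Parameters

Published material constants (never touched by calibration):

| structure | E (N/m²) |
|---|---|
| ossicles / "ossified" | 1.2 × 10¹⁰ |
| SAL | 6.5 × 10⁴ |
| AML | 2.1 × 10⁷ |
| PIL | 6.5 × 10⁵ |
| SIL, SML | 4.9 × 10⁶ |

LML and PML are not separately characterized; they default to the SML value
(same anatomical class) and are exposed in the configuration. Joint and
tendon moduli are likewise unprinted anywhere authoritative; the defaults
(IMJ 6 × 10⁶ Pa cartilage layer, ISJ 1.2 × 10⁸ Pa stiff lenticular
coupling, tendons 2.6 × 10⁶ Pa) keep the ossicular chain stiff relative to
the SAL so that annular-ligament stiffening is felt at the umbo — the
behaviour wideband tympanometry shows in otosclerosis.

Unprinted physical defaults, from standard middle-ear literature: malleus
25 mg, incus 28 mg, stapes 3 mg, tympanic-membrane effective mass 10 mg and
effective area 55 mm², footplate area 3.2 mm², baseline structural loss
factor 0.05 (SAL 0.10), cochlear resistance 0.2 N·s/m and compliance
10⁻² m/N. Element cross-sections and lengths are chosen so that the
suspension stiffness budget totals ≈1.0 × 10³ N/m at the malleus–incus
block and the SAL contributes ≈1.0 × 10³ N/m at the footplate.

## Calibration

Only unprinted parameters are calibration-adjustable. The routine
(`earmech.calibrate.calibrate_suspension`, CLI `earmech calibrate`) bisects
a single global scale on the suspension cross-section areas until the
umbo-velocity resonance of the normal model reaches a target inside the
800–1200 Hz physiological window, then reports the two constraint
scenarios: severe cord softening must resonate at or below ≈750 Hz
(dehiscence-like) and SAL ×10 at or above ≈1400 Hz (otosclerosis-like).
The shipped `data/normal_ear.yaml` is the frozen result (normal ≈ 928 Hz,
cord surrogate ≈ 638 Hz, SAL ×10 ≈ 2068 Hz) and is version-pinned; the
acceptance script recomputes these numbers from the file, never from
constants.

## Pathology layer

All manipulations act on element materials/cross-sections of a deep copy;
models are never mutated in place, and material copies are per-element so a
modification never leaks into a structure that shares a material definition.

* **Cord replacement** (incudostapedial dysplasia): the incus long-process
  element gets `E = 1.2 × 10¹⁰ × e_scale` with staged
  `e_scale ∈ {10⁻³, 10⁻⁴, 10⁻⁵}` and cross-section ¼ ("Ver1") or 1/16
  ("Ver2") of the normal area. 10⁻⁵ is the floor: a complete
  (zero-stiffness) discontinuity is outside the method's validity;
  off-enumeration values require `allow_custom`.
* **SAL scaling**: modulus × factor, or the bone value when "ossified".
* **Ligament fixation**: ×10 / ×100 / ×1000 or ossified. Staged multipliers
  are capped at the bone modulus: a fibro-osseous fixation cannot be stiffer
  than bone, and without the cap the AML ladder would invert (its ×1000
  value, 2.1 × 10¹⁰ Pa, exceeds the ossification value), breaking the
  physical rule that "ossified" is the most severe level.
* **Monopodal stapes**: anterior crus removed (idempotent; warning on
  repeat), posterior crus rebuilt as cord-like tissue with either a plain
  modulus or a generalized-Maxwell material. The default Maxwell parameters
  (E∞ = 1.2 × 10⁶ Pa, one arm 1.2 × 10⁸ Pa / 2 × 10⁻⁵ s) give a soft
  low-frequency cord that stiffens and dissipates toward 8 kHz; they are
  defaults, not asserted patient values.

The scenario catalog holds the six patient reconstructions (patient5's
composition {AML+SML ossified, SAL ×10} is labelled *illustrative* because
the clinical narrative is qualitative; patient6 uses ossified adhesion of
all six suspensory ligaments with the SAL untouched) plus the
single-ligament ossification sweep.

## Audiology layer

Simulated loss is compared to the measured **air–bone gap**, not raw air
thresholds: the model predicts conductive loss only. Sign conventions
follow clinical usage — *up-sloping* = loss concentrated at low frequencies
(stiffness pathologies), *down-sloping* = worse at high frequencies
(discontinuity/mass pathologies); the slope is a least-squares fit of loss
against log₂ frequency with threshold s₀ = 3 dB/octave, and an interior
point deviating more than d₀ = 10 dB from its neighbours' mean overrides
the label as peaked/dipped. Both thresholds are keyword-adjustable. PTA4
defaults to the unweighted mean of 500/1k/2k/4k Hz; the Japanese weighted
convention (500 + 2×1000 + 2000)/4 is selectable because the clinical
table's convention is unstated. Ranking sorts scenarios by RMS misfit on
the common grid, ties broken by higher Pearson r then catalog order; two
flat curves are defined as perfectly correlated (r = 1), one flat curve
against a varying one as r = 0.

## What the simulated data do and do not show

The recovery experiments generate "measured" gaps from the simulator itself
(plus seeded Gaussian noise of σ = 3 dB, the order of audiometric test–
retest variability). They demonstrate identifiability of the catalog under
the model's own physics — that the pathology families produce mutually
distinguishable curve shapes at audiometric resolution — not clinical
accuracy on real audiograms, which add bone-conduction error, calibration
steps per frequency, canal effects and inter-subject anatomical variance
that the generator does not emulate.

## Numerical choices

Sparse complex-symmetric assembly with `scipy.sparse` and `spsolve`
(cross-checked in tests against an independently written dense brute-force
solve at 10⁻⁸ relative tolerance and against the closed-form single
oscillator at 10⁻¹⁰); resonance search on a 512-point log grid over
200–4000 Hz followed by golden-section refinement to better than ±1 Hz
(relative tolerance below 500 Hz so sub-hertz test oscillators refine too),
ties toward the lower frequency; a boundary maximum is returned flagged
`no_resonance` instead of raising. A zero diseased |V_SF| yields a warned
+∞ sentinel clamped to 10⁶ dB so curve invariants (finiteness) hold.
Degenerate inputs (empty frequency lists, missing bone curves, < 4
overlapping frequencies, non-increasing CSV frequencies) raise typed errors
naming the offending value. Output CSVs carry `#` provenance headers
(version, config hash, seed) and are byte-deterministic.

## Limitations

One-dimensional piston kinematics (no rocking stapes modes, no tympanic
membrane modal breakup above ~4 kHz); ligament fixation stiffens elements
but adds no mass (granulation tissue or cholesteatoma loading is not
modelled); the external auditory canal is absent, which is exactly where
the patient6-type mismatch is expected; absolute |V_SF| values depend on
the calibrated unprinted parameters and only loss *ratios* should be
interpreted quantitatively.
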