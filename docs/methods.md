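# Methods

This note documents the model behind `alignersim`: what is simulated, the
reductions made relative to a full patient-specific finite-element
workflow, the parameters that matter, and what the synthetic scenario can
and cannot say about real treatment.

## Scenario

The package simulates the **premolar distalization stage** of staged
whole-arch distalization with clear aligners, on the right maxillary
quadrant only (the midline symmetry of the appliance is imposed as a
boundary condition, see below). The starting configuration has both molars
already distalized, leaving a 2.0 mm space between the second premolar and
the first molar. Ten staging steps then shorten the aligner span between
teeth 5 and 6 by 0.2 mm each (and lengthen the span between teeth 3 and 4
equally), prescribing 2.0 mm of distal bodily movement for both premolars.
A 150 gf (1.471 N) elastic runs from the buccal-mesial cervical region of
the canine socket to a buccal inter-radicular mini-implant between the
molars, 4 mm apical of the alveolar crest plane. Three trimline designs
are compared: full wrap (CON), second-molar half wrap (SMHW, no distal
wall on tooth 7), all-molar half wrap (MHW, no distal walls on teeth 6
and 7). Relapse is not modeled.

## Synthetic dentition

Patient CBCT segmentation is replaced by a parametric generator:

* **Arch**: quartic curve `y(x) = D(1 − (2x/W)^4)` in the occlusal plane
  (depth D = 42 mm, width W = 60 mm by default), teeth placed by arc
  length so that adjacent crowns share their contact point and the 2 mm
  gap sits between teeth 5 and 6.
* **Frame**: right-handed; occlusal plane Z = 0 with apical (gingival)
  positive, median sagittal plane X = 0, anterior +Y. The source workflow
  inherits its frame from earlier work without restating it, so these
  conventions are this package's own.
* **Crowns**: parametric boxes (mesio-distal widths 8.5/6.5/7.5/7.0/7.0/
  10.0/9.5 mm — generator plumbing, not measured anatomy).
* **Roots**: frusta of cones; molars get a 3 mm trunk plus three branches
  meeting at a furcation 3 mm apical of the cervix (which supports the
  "1 mm above the furcation" resistance-center landmark). Cervical radii
  are set so each tooth's lateral root area matches mean human root
  surface areas from the periodontal literature (≈204, 179, 273, 234,
  220, 433, 431 mm² for positions 1–7). Root *area* — not cross-section
  shape — is what sets PDL support stiffness, absolute tooth mobility and
  the creep per remodeling iteration, so it is the feature worth matching.
* Deterministic for a fixed seed; optional Gaussian landmark jitter
  (default off) exists only for robustness testing.

## PDL as a Winkler foundation

The 0.30 mm PDL layer is linear elastic (E = 0.67 MPa, ν = 0.45) and
reduced to independent surface springs: the confined (oedometric) modulus
over the thickness in the normal direction, the shear modulus over the
thickness tangentially:

```
k_n = E(1−ν)/[(1+ν)(1−2ν) t] ≈ 8.47 N/mm³
k_t = E/[2(1+ν) t]           ≈ 0.77 N/mm³
```

The bone side is rigid ground. Assembling `K = Σ Jᵢᵀ kᵢ Jᵢ` over the
sampled root surface (default 400 samples per tooth; K entries change by
< 1 % on refinement to 800) gives the 6×6 support operator used
everywhere. Strain is reported as spring elongation over thickness
(engineering strain); normal traction is positive in compression. Each
solve is small-displacement; finite motion accumulates across remodeling
iterations and steps, where poses are composed as exact rigid transforms.

This replaces a volumetric tetrahedral PDL mesh. It preserves total
support stiffness and the location of the center of resistance (checked
against an energy-Hessian oracle and a brute-force coupling-minimization
scan in the tests) but has no continuum stress tensor: the exported
per-sample traction field is a coarse analogue of a principal-stress plot,
not a replacement.

## Aligner reduction and socket stiffness

The 0.7 mm thermoformed shell (E = 1500 MPa) is reduced to a **rigid
frame** carrying one socket per crown — a deliberate, documented
simplification that keeps force transfer along the arch and the
wall-removal mechanism while dropping shell bending. Socket springs are
diagonal in the tooth's local frame; the mesio-distal component is a pair
of unilateral walls resolved by active-set sweeps (all walls start active;
any wall that would pull is deactivated; deterministic order, typically
stable within two sweeps).

Socket stiffness defaults are **calibration parameters** — a continuum
shell in frictional contact has no single recoverable spring value. The
shipped heuristic treats wall contact as through-thickness compression of
the shell over the engaged crown faces,

```
k_wall = E_a · (2 h_crown w_bl) / t_shell        (≈ 2–5·10^5 N/mm)
k_bl = k_vert = k_wall / 2
k_rot = k_wall · (h_crown² + w_bl²) / 4
```

with half-wrapped sockets halved and attachments multiplying vertical and
rotational grip by 1.5. The magnitude is chosen so that the aligner is
2–3 orders stiffer than the PDL, which is what makes one staging step
transfer essentially completely within two remodeling iterations — the
convergence property the whole staged procedure is predicated on (see
below). A beam-type estimate (`E_a t_shell h_crown / ℓ_span`, ~10³ N/mm)
was rejected: it leaves per-iteration relaxation ratios of 0.5–0.9 and the
staging never settles. All values are config-exposed.

The symmetry boundary condition reduces the frame to the three
mirror-invariant rigid motions: translations in the median sagittal plane
and rotation about its normal. The traction force is recomputed from
current geometry each solve and acts on the frame, not on any tooth;
whether the 150 gf acts per side or in total is not stated in the source —
per side is assumed, consistent with the half-arch model.

The temperature-changing method that physically realizes staged shape
changes in the source workflow is reproduced as bookkeeping only:
`t = (U − Δ)/(k d)` with the defaults k = 0.01 /°C and d = 2 mm, logged
per step and span. The engine consumes the rest-length change `U − Δ`
directly; the algebraic arrangement of the relation is inferred from the
symbol definitions (only those are published) and flagged as such.

## Remodeling loop and convergence

Each staging step runs `iterations_per_step = 2` cycles of
*solve equilibrium → set stress-free poses to equilibrium poses →
regenerate PDL*. Under a constant staged load the displacement increments
contract geometrically (ratio ≈ 0.01–0.1 per mode with the default socket
stiffness); a diagnostic third iteration (`check-convergence`, also the
quantity reported by `scripts/acceptance.py`) shows a maximum PDL strain
below 0.1 % of the layer thickness, i.e. the model is stabilized after
two iterations. The floor under that number (~0.09 %) is not numerical
residue but genuine creep: the TAD elastic is a constant force, so every
remodeling iteration converts it into a small rigid drift of the whole
arch — which is precisely how sustained orthodontic force moves teeth.

After the ten prescribed steps, identical extension steps continue until
the signed mesio-distal distance between the distal contact of tooth 5
and the mesial contact of tooth 6 falls below 0.01 mm (up to 8 extension
steps; a run that never closes raises, carrying the final gap).

## Measurement conventions

Per-tooth local frames: X = occlusal-plane projection of the mesial arch
tangent, Z = global occluso-gingival axis, Y = Z × X (lingual positive).
Reported quantities are the crown-point displacement components (mesial +,
lingual +, gingival +) and the components of the rotation vector of the
relative motion (lingual torque +, distal tipping +, mesial axial
rotation +), in degrees. The rotation vector is used instead of an Euler
sequence: below ~6° all sequences agree to < 0.01°, and the rotation
vector needs no ordering convention. Decomposition refuses rotations
beyond 30°. Efficiency of a prescribed tooth is
`100·max(0, −Δx_md)/2.0 %`; molar anchorage loss is
`100·max(0, +Δx_md)/2.0 %`; both clamped at zero (a `signed` flag exposes
raw values); design improvement is the difference of anchorage losses in
percentage points.

## What the synthetic scenario shows — and what it does not

The default run reproduces the mechanism, not patient-specific
magnitudes:

* anchorage-loss ordering SMHW > CON > MHW (removing only the
  second-molar wall concentrates the mesial push on the first molar;
  removing both nearly eliminates it),
* anterior labial/mesial displacement ordering MHW > SMHW > CON (the
  counterforce has to go somewhere),
* space closure latest for MHW (the gap no longer closes from the molar
  side), CON ≤ SMHW ≤ MHW,
* MHW molars never receive a mesially directed socket force, by
  construction of the unilateral walls.

Absolute displacements depend on the synthetic anatomy and the calibrated
socket stiffness; with the defaults the space-closed steps come out
10/10/16 and premolar efficiencies ≈ 80/73/99 % for CON/SMHW/MHW.
Quantities this model cannot deliver: intra-crown strain, shell stress,
frictional slip, hyperelastic/viscoelastic PDL response, relapse, and any
patient-specific prediction. Passing tests demonstrate internal
consistency and the trimline mechanism under the stated reductions — not
clinical accuracy.

## Numerical choices

* Direct dense solves (≤ 45 DOF); singular systems raise with the
  unconstrained subspace named, never silently regularized.
* Active-set tie-break: sockets in position order, mesial wall before
  distal; oscillation detection raises with the offending socket ids.
* Space-closed tolerance 0.01 mm; residual tolerances 1e-6 N / 1e-5 N·mm.
* Root-surface quadrature: midpoint rule in (axis, angle); exact for the
  linear frustum radius, so sampled areas match closed-form lateral areas
  to round-off and are pose-invariant by construction.
* Problem sizes used by the shipped tests and the acceptance script:
  400 PDL samples per tooth, 10 + ≤ 8 staging steps, 2 iterations per
  step — a deliberate desk-scale configuration; every quantity reported
  by the package is computed at these sizes.
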