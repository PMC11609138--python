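# Example scenario configuration for `alignersim run` / `alignersim compare`.
# Every key is optional; omitted keys fall back to the study defaults shown
# here.  Lengths in mm, forces in gram-force, moduli are fixed in code
# (PDL E = 0.67 MPa, nu = 0.45; aligner E = 1500 MPa, nu = 0.30).

seed: 0
design: con              # con | smhw | mhw (used by `run`)
designs: [con, smhw, mhw]   # used by `compare` when --designs is not given
traction_gf: 150         # elastic traction, canine hook -> mini-implant

dentition:
  gap_premolar2_molar1: 2.0   # post-molar-distalization space, teeth 5-6
  pdl_thickness: 0.30         # periodontal-ligament layer thickness
  alveolar_crest_level: 10.0  # crest plane depth below the occlusal plane
  jitter_sigma: 0.0           # optional Gaussian landmark jitter (robustness)

staging:
  n_steps: 10            # prescribed staging steps
  step_increment: 0.2    # distal socket translation per step, both premolars

engine:
  iterations_per_step: 2     # bone-remodeling iterations per staging step
  space_closed_tolerance: 0.01
  max_extension_steps: 8     # extra identical steps allowed after step 10
  pdl_samples_per_tooth: 400
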