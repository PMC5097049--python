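# Hookean force-field parameter set, version 1.
#
# All parameters are data, not code: the Lennard-Jones table, the phi/psi
# Gaussian-well map and the torsional constants may be replaced wholesale.
# Any comparison against published numbers must state which parameter file
# produced it.  Units: kcal/mol, Å, amu, degrees (angles in this file).
version: 1
lj:
  # Per-element united-heavy-atom classes. sigma in Å; epsilon in kcal/mol
  # (the inflection-point cutoff (26/7)^(1/6)·sigma_ij is epsilon-independent).
  sigma: {C: 3.80, N: 3.55, O: 3.45, S: 4.00}
  epsilon: {C: 0.12, N: 0.16, O: 0.20, S: 0.25}
  combine: arithmetic        # sigma_ij = (sigma_i + sigma_j) / 2
nbi:
  profile: constant          # "constant" | "lj_curvature"
  k: 1.0                     # spring constant, kcal/mol/Å^2 (constant profile)
  global_scale: 1.0          # multiplies every NBI stiffness
torsion:
  k_chi: 6.0                 # harmonic side-chain torsion constant, kcal/mol/rad^2
  curvature_floor: 0.5       # minimum phi/psi stiffness, kcal/mol/rad^2
  # Ramachandran-style map: E(phi, psi) = -sum_m depth_m *
  #   exp(-((phi-phi_m)^2 + (psi-psi_m)^2) / width_m^2), widths in degrees.
  phipsi_wells:
    - {phi: -63.0,  psi: -43.0, depth: 2.0, width: 30.0}
    - {phi: -120.0, psi: 135.0, depth: 2.2, width: 35.0}
    - {phi: 57.0,   psi: 47.0,  depth: 0.5, width: 25.0}
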