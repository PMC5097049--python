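# Methods

## Model and assumptions

The deposited (or generated) conformation is taken to be a stable minimum of
the intramolecular energy. Every interaction is therefore modeled as a spring
at rest at that geometry, so the energy and gradient vanish there exactly and
the potential matrix is positive semidefinite by construction. The analysis
is restricted to a reduced heavy-atom representation (no hydrogens, no
ligands, no solvent) of isolated chains: inter-monomer and lattice modes are
outside the model, which matters when computed B-factors are compared with
crystallographic ones (those include crystal-contact and anharmonic
contributions).

Mobile coordinates are the soft dihedrals only:

* ϕ = (C⁻, N, Cα, C), absent at the first residue of every resolved range and
  frozen for proline (the ring closes over the N–Cα bond);
* ψ = (N, Cα, C, N⁺); at the C-terminal residue the OXT oxygen substitutes
  for the missing next amide nitrogen so that every residue carries a ψ;
* χ: one torsion per rotatable side-chain single bond with at least one
  further heavy atom on each side, as enumerated residue-by-residue in the
  template table. Aromatic rings, guanidinium, carboxylate and amide groups
  are rigid plates (the bond that rotates the plate as a whole is soft; plate
  internals are not). Hydroxyl/thiol torsions do not exist because hydrogens
  are not represented. ω and ring-internal torsions are frozen; any torsion
  whose central bond lies inside a covalent ring — including backbone
  torsions trapped inside a disulfide loop — is frozen rather than treated
  with ring-closure constraint algebra.

## Degrees-of-freedom bookkeeping

For an N-atom chain the topology reports |bonds| (template bonds + peptide
bonds within each resolved range + OXT + disulfides under 2.5 Å), all-pairs
bond angles, and the torsional remainder `dihedral_dof = 3N − 6 − |bonds| −
|angles|`. The remainder convention is deliberate: with branching, all-pairs
angle enumeration is redundant against an independent internal-coordinate
set, so the enumerated proper-torsion paths (kept in `Topology.dihedrals` for
bookkeeping) exceed the number of independent torsional coordinates. The
remainder is the count that makes the three numbers a partition of the 3N − 6
internal degrees of freedom.

## Force field (all parameters are versioned data)

`data/forcefield.yaml` ships the defaults; any published-number comparison
should state which parameter file produced it.

* **LJ classes.** One united-heavy-atom class per element (C/N/O/S), combined
  arithmetically. The cutoff is the inflection point of the 6–12 curve,
  (26/7)^(1/6)·σᵢⱼ ≈ 1.244·σᵢⱼ — beyond it the curvature of the parent
  potential is negative and a distance spring is no longer meaningful. The
  inequality at the cutoff is strict.
* **NBI stiffness.** Default: one uniform constant k = 1 kcal/mol/Å² inside
  the cutoff (simplest profile satisfying positivity and monotonicity). A
  |V″_LJ(d₀)|-proportional profile (clamped below r_min so the repulsive rise
  is not amplified) is available via `nbi.profile: lj_curvature`.
* **ϕ/ψ map.** E(ϕ,ψ) = −Σ A_m exp(−((ϕ−ϕ_m)² + (ψ−ψ_m)²)/w_m²) with three
  wells (α-helical, β, left-handed-α). The torsional spring constant is the
  map curvature along ϕ or ψ at the residue's deposited pair, floored at
  0.5 kcal/mol/rad² so a structure sitting on a map ridge never receives a
  negative stiffness. At the center of an isolated well the curvature is
  2A/w², which the tests verify analytically.
* **χ springs.** One harmonic constant, default 6 kcal/mol/rad², the order of
  a 3 kcal/mol threefold barrier's curvature at its minimum.
* **Units.** Energy kcal/mol, length Å, mass amu; the single conversion to
  spectroscopic wavenumbers, √(1 kcal/mol/(amu·Å²))/(2πc) ≈ 108.59 cm⁻¹,
  lives in `constants.py` and is validated against a closed-form rigid rotor
  using scipy's CODATA constants.
* **Global frequency scale.** `nbi.global_scale` multiplies every NBI spring;
  eigenvectors are invariant under it and frequencies scale as its square
  root. It is the single knob for calibrating the absolute frequency axis
  against a reference spectrum and defaults to 1.

## Eigenproblem

The rotor set of a torsion is the connected component on the far side of its
central bond; raw Jacobian columns are r̂ × (x_a − p) there and zero
elsewhere. Rigid-body handling is by mass-weighted projection of the six
translation/rotation fields out of every column (rather than constraint
elimination), which keeps the potential-matrix assembly a pure sum over
springs and makes the zero-momentum property of every mode field directly
testable. F and H are assembled densely and solved with a dense symmetric
generalized eigensolver — torsional problems of a few thousand DOF are
desk-scale. Eigenvector signs are fixed by making the largest-magnitude
torsional component positive. Wavenumbers below 1e-4 cm⁻¹ are treated as
numerical zeros and raise: none should survive the projection.

## Thermal profiles

Classical occupation (no ℏω/kT correction): ⟨q_k²⟩ = k_BT/ω_k². The default
activation temperature follows the reference conditions at 180 K. The
"contribution of a mode subset to the total" is reported primarily as the
ratio of summed per-Cα RMSF (subset over all modes); the quadrature
alternative (ratio of summed mean-square displacements) is always computed
alongside. B-factor comparisons are unscaled — no least-squares rescaling
before correlation or region averages.

## Morphing

Deformation adds Σ a_k v_k to the soft dihedral values and rebuilds
coordinates exactly (every bond length and angle preserved to machine
precision), then rigid-superposes onto the input; linear Cartesian
extrapolation exists behind a flag for diagnostics. Amplitude fitting is
deterministic: a fixed lattice of starts (each amplitude at 0, ±0.5, ±1, ±2
peak thermal amplitudes, where the peak amplitude √(2k_BT)/ω carries k_BT of
energy) followed by Nelder-Mead refinement of the best three, with the
k-mode search seeded by the (k−1)-mode optimum so the fitted RMSD is
non-increasing in k. A sequential one-mode-at-a-time variant supports
per-mode energy bookkeeping. "Relative contribution" of mode k is
|a_k|·‖field_k‖ normalized to sum to one (the squared-norm alternative is
reported in the same result object). The default fit selection is the
main-chain heavy atoms N, Cα, C, O, paired by residue number with pairwise
exclusion of unresolved residues.

The clash scan displaces each assembly chain along its own isolated-monomer
modes at ±1 peak thermal amplitude, enumerates all sign combinations
congruently across chains, and counts inter-chain heavy-atom pairs under the
threshold (default 2.4 Å) against the deposited baseline.

## Region map

`data/regions.yaml` fixes the anchors: head (α24–94/β9–77), arm
(α116–150/β103–137), fist (α151–155/β138–143), lid (β417–433), strut
(α430–440), posterior surface (α169–229/β157–214), P-loop
(α169–177/β156–163). The torso/foot split at the arginine finger (α373/β356)
and the torso complement are editable defaults. Nesting: posterior and
P-loop sit inside the torso; lid/strut inside the foot. Note that the β
P-loop as printed starts one residue before the posterior interval, so only
torso containment holds exactly. Cleft-distance diagnostics (specific CZ/CD
atom pairs) are exposed through `caliper_distance` but are regression
diagnostics, not acceptance gates, because they depend on the mode-amplitude
convention.

## Synthetic data

`build_peptide` constructs heavy-atom chains from internal coordinates (NeRF
chain extension) using the ideal-geometry entries of the template table; ϕ/ψ
and χ round-trip to the requested values below 1e-6°, and all twenty standard
residues build with L-chirality (verified by the N/C/Cβ triple product).
`build_dumbbell` joins two ideal poly-Ala helices with an extended Gly
linker: its slowest modes are hinge bends, giving a controllable two-domain
system. `perturb_along_torsions` creates conformer pairs with exact known
torsional displacements for ground-truth recovery tests. What these systems
do *not* emulate: realistic side-chain packing density (the dumbbell's
mean NBI degree is below a globular protein's first-shell value), rotamer
statistics, and crystallographic noise — so passing tests demonstrate the
correctness of the machinery and its invariants, not force-field realism on
real proteins.

## Problem sizes and numerical choices

The default suite runs on the 113-atom dumbbell (45 torsions), a tripeptide
(10 torsions) and an 8-atom rotor toy; the full pipeline on these sizes takes
seconds, and the crystal-structure tier (≈1830 torsions per chain, dense
eigenproblem) activates only when a local coordinate file is present.
Finite-difference oracles use Δθ = 1e-5 rad (Jacobian) and 1e-4 rad (Hessian,
5-point/mixed stencils). Caliper cycles are sampled at 16 phases. Alt-loc
collapse defaults to highest occupancy with label-order tie-break. Kabsch
superposition enforces a proper rotation via the SVD determinant correction.

## Known limitations

No electrostatics, hydrogen bonding, solvent or ligand terms; no anharmonic
corrections; no ring-closure algebra (ring-locked torsions are frozen); B
comparisons ignore inter-monomer and lattice contributions; the absolute
frequency axis depends on the shipped spring constants through the single
global scale.
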