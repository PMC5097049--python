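"""Jacobian, matrix assembly and eigensolution against independent oracles."""

import math

import numpy as np
import pytest
import scipy.constants
import scipy.linalg

import torsnma as t
from torsnma.config import ForceFieldParams
from torsnma.forcefield import SpringSystem, TorsionTerm
from torsnma.geometry import rotation_about_axis
from torsnma.nma_engine import build_matrices, dihedral_jacobian, solve_modes
from torsnma.structure_io import AtomRecord, ChainModel
from torsnma.topology import SoftDihedral, Topology


def _weighted_kabsch_displacement(moved, ref, masses):
    """Small displacement field of ``moved`` relative to ``ref`` after optimal
    mass-weighted rigid superposition (independent of the engine's Eckart
    projector)."""
    w = masses / masses.sum()
    cm = (w[:, None] * moved).sum(0)
    cr = (w[:, None] * ref).sum(0)
    H = ((moved - cm) * masses[:, None]).T @ (ref - cr)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return (moved - cm) @ R.T + cr - ref


def _spring_energy(analysis, deltas):
    moved = t.perturb_along_torsions(analysis.chain, analysis.topology, deltas)
    c = moved.coords
    e = 0.0
    for term in analysis.springs.nbi:
        d = np.linalg.norm(c[term.atom_i] - c[term.atom_j])
        e += 0.5 * term.stiffness * (d - term.rest_length) ** 2
    for tt, dth in zip(analysis.springs.torsional, deltas):
        e += 0.5 * tt.stiffness * dth**2
    return e


def _toy_rotor(r_a=1.0, r_b=1.2, k_t=3.0):
    """Ethane-like rigid rotor: two 3-fold symmetric caps on a z-axis bond.

    Returns (chain, topology, springs, I_a, I_b) with cap inertias about the
    bond axis in internal units."""
    coords = [(0.0, 0.0, 0.0), (0.0, 0.0, 1.5)]
    names = ["C1", "C2"]
    for k in range(3):
        ang = 2 * math.pi * k / 3
        coords.append((r_a * math.cos(ang), r_a * math.sin(ang), -0.5))
        names.append(f"A{k}")
    for k in range(3):
        ang = 2 * math.pi * k / 3 + 0.4
        coords.append((r_b * math.cos(ang), r_b * math.sin(ang), 2.0))
        names.append(f"B{k}")
    atoms = [
        AtomRecord(i + 1, nm, "C", "", 1.0, xyz, 0.0, 1, "LIG", "T")
        for i, (nm, xyz) in enumerate(zip(names, coords))
    ]
    chain = ChainModel(chain_id="T", atoms=atoms, source_id="toy-rotor")
    bonds = [(0, 1)] + [(0, i) for i in (2, 3, 4)] + [(1, i) for i in (5, 6, 7)]
    adjacency = [[] for _ in range(8)]
    for i, j in bonds:
        adjacency[i].append(j)
        adjacency[j].append(i)
    sd = SoftDihedral("chi", (2, 0, 1, 5), 1, 1, 0.0, frozenset({1, 5, 6, 7}))
    topo = Topology(8, bonds, [], [], [sd], adjacency)
    params = ForceFieldParams(lj_sigma={"C": 3.8}, lj_epsilon={"C": 0.1})
    springs = SpringSystem(nbi=[], torsional=[TorsionTerm(sd, 0.0, k_t, "chi_harmonic")],
                           params=params)
    m = chain.masses[0]
    return chain, topo, springs, 3 * m * r_a**2, 3 * m * r_b**2


class TestJacobian:
    def test_columns_match_finite_difference_after_superposition(self, tripeptide_analysis):
        """Central difference of the exact torsional rebuild, superposed back
        mass-weighted, reproduces every Eckart-projected column."""
        an = tripeptide_analysis
        jac = an.jacobian
        n = jac.n_soft
        masses = an.chain.masses
        h = 1e-5
        for j in range(n):
            d = np.zeros(n)
            d[j] = h
            plus = t.perturb_along_torsions(an.chain, an.topology, d).coords
            minus = t.perturb_along_torsions(an.chain, an.topology, -d).coords
            ref = an.chain.coords
            fd = (
                _weighted_kabsch_displacement(plus, ref, masses)
                - _weighted_kabsch_displacement(minus, ref, masses)
            ) / (2 * h)
            col = jac.projected[:, j].reshape(-1, 3)
            assert np.abs(fd - col).max() < 1e-5

    def test_raw_columns_match_finite_difference_exactly(self, tripeptide_analysis):
        an = tripeptide_analysis
        n = an.jacobian.n_soft
        h = 1e-6
        for j in range(0, n, 2):
            d = np.zeros(n)
            d[j] = h
            plus = t.perturb_along_torsions(an.chain, an.topology, d).coords
            minus = t.perturb_along_torsions(an.chain, an.topology, -d).coords
            fd = (plus - minus) / (2 * h)
            col = an.jacobian.raw[:, j].reshape(-1, 3)
            assert np.abs(fd - col).max() < 1e-6

    def test_raw_columns_vanish_outside_rotor_set(self, tripeptide_analysis):
        an = tripeptide_analysis
        for j, sd in enumerate(an.topology.soft_dihedrals):
            col = an.jacobian.raw[:, j].reshape(-1, 3)
            outside = [i for i in range(len(an.chain.atoms)) if i not in sd.rotor]
            assert np.all(col[outside] == 0.0)

    def test_projected_columns_mass_orthogonal_to_rigid_fields(self, dumbbell_analysis):
        jac = dumbbell_analysis.jacobian
        masses = jac.masses
        coords = jac.coords
        com = np.average(coords, axis=0, weights=masses)
        w = np.repeat(masses, 3)
        fields = []
        for k in range(3):
            f = np.zeros((len(masses), 3))
            f[:, k] = 1.0
            fields.append(f.reshape(-1))
        for axis in np.eye(3):
            fields.append(np.cross(axis, coords - com).reshape(-1))
        for f in fields:
            overlap = np.abs(jac.projected.T @ (w * f)) / np.linalg.norm(f)
            assert overlap.max() < 1e-8

    def test_single_rotor_column_is_cross_product(self):
        chain, topo, _, _, _ = _toy_rotor()
        jac = dihedral_jacobian(chain, topo)
        coords = chain.coords
        axis = (coords[1] - coords[0]) / np.linalg.norm(coords[1] - coords[0])
        for a in (5, 6, 7):
            expected = np.cross(axis, coords[a] - coords[1])
            assert np.allclose(jac.raw[3 * a : 3 * a + 3, 0], expected, atol=1e-10)


class TestMatrices:
    def test_zero_springs_give_zero_potential(self, tripeptide_analysis):
        an = tripeptide_analysis
        params = an.springs.params
        zero_tors = [TorsionTerm(tt.dihedral, tt.rest_angle, 0.0, tt.origin)
                     for tt in an.springs.torsional]
        F, H = build_matrices(an.jacobian, SpringSystem([], zero_tors, params))
        assert np.all(F == 0.0)
        assert np.all(np.linalg.eigvalsh(H) > 0)

    def test_potential_matrix_matches_finite_difference_hessian(self, tripeptide_analysis):
        """5-point/mixed finite differences of the explicit spring energy."""
        an = tripeptide_analysis
        F, _ = build_matrices(an.jacobian, an.springs)
        n = F.shape[0]
        h = 1e-4
        F_fd = np.zeros_like(F)
        for i in range(n):
            for s, coef in ((2, -1.0), (1, 16.0), (0, -30.0), (-1, 16.0), (-2, -1.0)):
                d = np.zeros(n)
                d[i] = s * h
                F_fd[i, i] += coef * _spring_energy(an, d)
            F_fd[i, i] /= 12 * h**2
            for j in range(i + 1, n):
                acc = 0.0
                for si, sj, coef in ((1, 1, 1.0), (1, -1, -1.0), (-1, 1, -1.0), (-1, -1, 1.0)):
                    d = np.zeros(n)
                    d[i], d[j] = si * h, sj * h
                    acc += coef * _spring_energy(an, d)
                F_fd[i, j] = F_fd[j, i] = acc / (4 * h**2)
        scale = np.abs(F).max()
        denom = np.maximum(np.abs(F), 1e-5 * scale)
        assert (np.abs(F_fd - F) / denom).max() < 1e-4

    def test_kinetic_matrix_of_rigid_rotor_is_reduced_inertia(self):
        chain, topo, springs, I_a, I_b = _toy_rotor()
        jac = dihedral_jacobian(chain, topo)
        _, H = build_matrices(jac, springs)
        # raw (unprojected) kinetic term: full cap inertia about the axis
        w = np.repeat(chain.masses, 3)
        H_raw = jac.raw.T @ (jac.raw * w[:, None])
        assert H_raw[0, 0] == pytest.approx(I_b, rel=1e-12)
        # Eckart projection leaves the two-cap reduced moment of inertia
        assert H[0, 0] == pytest.approx(I_a * I_b / (I_a + I_b), rel=1e-10)


class TestSolveModes:
    def test_one_dof_rotor_closed_form_frequency_and_unit_conversion(self):
        """nu = sqrt(k/I)/(2 pi c), conversion computed here from
        scipy.constants, independently of the package constants."""
        k_t = 3.0  # kcal/mol/rad^2
        chain, topo, springs, I_a, I_b = _toy_rotor(k_t=k_t)
        jac = dihedral_jacobian(chain, topo)
        F, H = build_matrices(jac, springs)
        modes = solve_modes(F, H, jac)
        I_red = I_a * I_b / (I_a + I_b)
        kcal_per_molecule = scipy.constants.calorie * 1000 / scipy.constants.N_A
        omega_si = math.sqrt(
            (k_t * kcal_per_molecule)
            / (I_red * scipy.constants.atomic_mass * 1e-20)
        )
        nu_cm = omega_si / (2 * math.pi * scipy.constants.c * 100)
        # tolerance covers CODATA-vintage differences in the amu value
        assert modes.frequencies_cm[0] == pytest.approx(nu_cm, rel=1e-8)

    def test_spectrum_oracle_cartesian_hessian_projection(self, dumbbell_analysis):
        """Independent route: assemble the full 3N x 3N Cartesian Hessian of
        the spring network, project with the Jacobian, and solve."""
        an = dumbbell_analysis
        coords = an.chain.coords
        n = len(an.chain.atoms)
        K = np.zeros((3 * n, 3 * n))
        for term in an.springs.nbi:
            i, j = term.atom_i, term.atom_j
            u = coords[i] - coords[j]
            u /= np.linalg.norm(u)
            blk = term.stiffness * np.outer(u, u)
            K[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += blk
            K[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += blk
            K[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= blk
            K[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= blk
        J = an.jacobian.projected
        F_oracle = J.T @ K @ J + np.diag([tt.stiffness for tt in an.springs.torsional])
        evals = scipy.linalg.eigh(F_oracle, an.modes.kinetic_matrix, eigvals_only=True)
        assert np.allclose(evals, an.modes.eigenvalues, rtol=1e-6)

    def test_spectrum_invariant_under_rigid_rotation(self, dumbbell_chain, dumbbell_analysis):
        R = rotation_about_axis(np.array([1.0, -0.3, 0.8]), 1.234)
        moved = dumbbell_chain.with_coords(dumbbell_chain.coords @ R.T + 5.0)
        moved_modes = t.analyze_chain(moved).modes
        diff = np.abs(moved_modes.frequencies_cm - dumbbell_analysis.modes.frequencies_cm)
        assert diff.max() < 1e-6

    def test_uniform_potential_scaling_law(self, tripeptide_analysis):
        an = tripeptide_analysis
        F, H = build_matrices(an.jacobian, an.springs)
        m1 = solve_modes(F, H, an.jacobian)
        m2 = solve_modes(2 * F, H, an.jacobian)
        assert np.allclose(m2.frequencies_cm, math.sqrt(2) * m1.frequencies_cm, rtol=1e-10)
        assert np.allclose(np.abs(m2.torsional_vectors), np.abs(m1.torsional_vectors), atol=1e-8)

    def test_doubling_global_scale_scales_frequencies_by_sqrt2(self, dumbbell_chain):
        from torsnma.config import load_forcefield_params
        import dataclasses as dc

        base = load_forcefield_params()
        # double every stiffness, torsional and nonbonded alike
        doubled = dc.replace(
            base,
            global_scale=2.0 * base.global_scale,
            k_chi=2.0 * base.k_chi,
            curvature_floor=2.0 * base.curvature_floor,
            phipsi_wells=tuple(dc.replace(w, depth=2.0 * w.depth) for w in base.phipsi_wells),
        )
        m1 = t.analyze_chain(dumbbell_chain).modes
        m2 = t.analyze_chain(dumbbell_chain, params=doubled).modes
        assert np.allclose(m2.frequencies_cm, math.sqrt(2) * m1.frequencies_cm, rtol=1e-8)

    def test_mode_fields_carry_no_momentum(self, dumbbell_analysis):
        m = dumbbell_analysis.modes
        coords = dumbbell_analysis.jacobian.coords
        com = np.average(coords, axis=0, weights=m.masses)
        for k in range(min(10, m.n_modes)):
            f = m.cartesian_fields[k]
            lin = (m.masses[:, None] * f).sum(0)
            ang = (m.masses[:, None] * np.cross(coords - com, f)).sum(0)
            assert np.abs(lin).max() < 1e-8
            assert np.abs(ang).max() < 1e-8

    def test_generalized_mass_orthonormality(self, dumbbell_analysis):
        m = dumbbell_analysis.modes
        V = m.torsional_vectors
        gram = V.T @ m.kinetic_matrix @ V
        assert np.abs(gram - np.eye(V.shape[1])).max() < 1e-8

    def test_all_frequencies_strictly_positive(self, dumbbell_analysis):
        assert np.all(dumbbell_analysis.modes.frequencies_cm > 1e-4)
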