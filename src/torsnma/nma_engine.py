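"""Torsional normal mode engine.

The mobile coordinates are the soft dihedrals theta.  The Cartesian
displacement field of torsion j is the infinitesimal rotation of its rotor-set
atoms about the central bond axis,

    d x_a / d theta_j = r_hat_j x (x_a - p_j)   for a in rotor(j), else 0,

with the mass-weighted rigid-body component (net translation and rotation
about the center of mass; the Eckart conditions) projected out of every
column.  At a minimum of a spring network the potential matrix is a pure sum
over springs,

    F_jk = sum_t k_t (dd_t/dtheta_j)(dd_t/dtheta_k) + delta_jk k_j^tors,

and the kinetic matrix is H = J^T M J.  The generalized symmetric eigenproblem
F v = omega^2 H v yields frequencies (reported as wavenumbers, cm^-1) and
torsional eigenvectors, H-orthonormal by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .config import ForceFieldParams, load_forcefield_params
from .constants import WAVENUMBER_PER_SQRT_INTERNAL
from .forcefield import SpringSystem, build_springs
from .structure_io import ChainModel
from .topology import Topology, build_topology

#: wavenumbers below this are numerical zeros; none should survive projection
ZERO_MODE_WAVENUMBER = 1e-4


@dataclass
class TorsionalJacobian:
    """Cartesian derivative fields of the soft dihedrals, shape (3N, n_soft)."""

    raw: np.ndarray
    projected: np.ndarray
    masses: np.ndarray
    coords: np.ndarray

    @property
    def n_soft(self) -> int:
        return self.raw.shape[1]


def _rigid_fields(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-orthonormal basis of the 6 rigid-body displacement fields."""
    n = coords.shape[0]
    com = np.average(coords, axis=0, weights=masses)
    rel = coords - com
    fields = np.zeros((3 * n, 6))
    for k in range(3):
        fields[k::3, k] = 1.0  # translations
    for k, axis in enumerate(np.eye(3)):
        rot = np.cross(np.broadcast_to(axis, (n, 3)), rel)
        fields[:, 3 + k] = rot.reshape(-1)
    # Gram-Schmidt under the mass metric
    w = np.repeat(masses, 3)
    ortho = []
    for k in range(6):
        v = fields[:, k].copy()
        for u in ortho:
            v -= u * np.dot(w * u, v)
        norm = np.sqrt(np.dot(w * v, v))
        if norm > 1e-10:
            ortho.append(v / norm)
    return np.column_stack(ortho)


def dihedral_jacobian(chain: ChainModel, topology: Topology) -> TorsionalJacobian:
    """Raw rotor-set derivative columns and their Eckart-projected versions."""
    coords = chain.coords
    masses = chain.masses
    n = coords.shape[0]
    soft = topology.soft_dihedrals
    raw = np.zeros((3 * n, len(soft)))
    for j, sd in enumerate(soft):
        _, b, c, _ = sd.atom_quad
        axis = coords[c] - coords[b]
        norm = np.linalg.norm(axis)
        if norm < 1e-8:
            raise ValueError(f"zero-length bond axis for dihedral {sd}")
        axis /= norm
        rotor = sorted(sd.rotor)
        disp = np.cross(axis, coords[rotor] - coords[c])
        col = np.zeros((n, 3))
        col[rotor] = disp
        raw[:, j] = col.reshape(-1)

    rigid = _rigid_fields(coords, masses)
    w = np.repeat(masses, 3)
    # subtract mass-weighted projections onto the rigid fields
    coeffs = rigid.T @ (raw * w[:, None])
    projected = raw - rigid @ coeffs
    return TorsionalJacobian(raw=raw, projected=projected, masses=masses, coords=coords)


def build_matrices(
    jacobian: TorsionalJacobian, springs: SpringSystem, masses: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the potential matrix F and kinetic matrix H (n_soft x n_soft)."""
    masses = jacobian.masses if masses is None else np.asarray(masses, dtype=float)
    J = jacobian.projected
    coords = jacobian.coords
    n_soft = jacobian.n_soft

    # distance-spring derivative rows: G[t, j] = u_hat_t . (Jcol_i - Jcol_j)
    if springs.nbi:
        ii = np.array([t.atom_i for t in springs.nbi])
        jj = np.array([t.atom_j for t in springs.nbi])
        kk = np.array([t.stiffness for t in springs.nbi])
        u = coords[ii] - coords[jj]
        u /= np.linalg.norm(u, axis=1)[:, None]
        Ji = J.reshape(-1, 3, n_soft)[ii]  # (T, 3, n_soft)
        Jj = J.reshape(-1, 3, n_soft)[jj]
        G = np.einsum("td,tds->ts", u, Ji - Jj)
        F = (G * kk[:, None]).T @ G
    else:
        F = np.zeros((n_soft, n_soft))
    if len(springs.torsional) != n_soft:
        raise ValueError("one torsional term per soft dihedral is required")
    F[np.diag_indices_from(F)] += np.array([t.stiffness for t in springs.torsional])
    F = 0.5 * (F + F.T)

    w = np.repeat(masses, 3)
    H = J.T @ (J * w[:, None])
    H = 0.5 * (H + H.T)
    # guard against a torsion with an empty effective rotor
    diag = np.diag(H)
    if np.any(diag < 1e-12):
        bad = int(np.argmin(diag))
        raise ValueError(
            f"kinetic matrix singular: soft dihedral #{bad} moves (almost) no mass"
        )
    return F, H


@dataclass
class ModeSet:
    """Eigenfrequencies and mode shapes of one chain."""

    frequencies_cm: np.ndarray  # ascending wavenumbers, cm^-1
    eigenvalues: np.ndarray  # omega^2 in internal units
    torsional_vectors: np.ndarray  # (n_soft, n_modes), H-orthonormal columns
    cartesian_fields: np.ndarray  # (n_modes, N, 3), mass-generalized-normalized
    kinetic_matrix: np.ndarray
    masses: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.frequencies_cm)


def solve_modes(F: np.ndarray, H: np.ndarray,
                jacobian: TorsionalJacobian | None = None) -> ModeSet:
    """Solve F v = omega^2 H v; eigenvector sign fixed so the largest-magnitude
    torsional component is positive."""
    evals, vecs = scipy.linalg.eigh(F, H)
    # numerically tiny negatives are zero
    evals = np.where(np.abs(evals) < 1e-12, 0.0, evals)
    if np.any(evals < 0):
        raise ValueError(f"negative eigenvalue {evals.min():.3e}: F not PSD")
    freqs = np.sqrt(evals) * WAVENUMBER_PER_SQRT_INTERNAL
    if np.any(freqs < ZERO_MODE_WAVENUMBER):
        n_zero = int(np.sum(freqs < ZERO_MODE_WAVENUMBER))
        raise ValueError(
            f"{n_zero} numerically zero mode(s) (< {ZERO_MODE_WAVENUMBER} cm^-1) "
            "survived rigid-body projection; check the spring system"
        )
    for k in range(vecs.shape[1]):
        lead = np.argmax(np.abs(vecs[:, k]))
        if vecs[lead, k] < 0:
            vecs[:, k] = -vecs[:, k]
    if jacobian is not None:
        n_atoms = jacobian.coords.shape[0]
        fields = (jacobian.projected @ vecs).T.reshape(-1, n_atoms, 3)
        masses = jacobian.masses
    else:
        fields = np.zeros((len(freqs), 0, 3))
        masses = np.array([])
    return ModeSet(
        frequencies_cm=freqs,
        eigenvalues=evals,
        torsional_vectors=vecs,
        cartesian_fields=fields,
        kinetic_matrix=H,
        masses=masses,
    )


@dataclass
class ChainAnalysis:
    """Bundle of everything the downstream reports need for one chain."""

    chain: ChainModel
    topology: Topology
    springs: SpringSystem
    jacobian: TorsionalJacobian
    modes: ModeSet


def analyze_chain(
    chain: ChainModel,
    params: ForceFieldParams | None = None,
    topology: Topology | None = None,
) -> ChainAnalysis:
    """Run the full pipeline: topology -> springs -> Jacobian -> modes."""
    params = params or load_forcefield_params()
    topo = topology or build_topology(chain)
    springs = build_springs(chain, topo, params)
    jac = dihedral_jacobian(chain, topo)
    F, H = build_matrices(jac, springs)
    modes = solve_modes(F, H, jac)
    return ChainAnalysis(chain=chain, topology=topo, springs=springs,
                         jacobian=jac, modes=modes)
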