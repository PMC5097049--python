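"""Hookean spring system about the deposited geometry.

The deposited conformation is taken as the energy minimum, so every term is a
spring at rest there and the total energy and gradient are exactly zero by
construction.  Two families of terms exist:

* nonbonded interactions (NBIs): distance springs between atom pairs more than
  3 covalent bonds apart and closer than the inflection point of their
  Lennard-Jones 6-12 curve, r_infl = (26/7)^(1/6) * sigma_ij;
* torsional springs on every soft dihedral: phi/psi stiffness is the local
  curvature of a Ramachandran-style sum-of-Gaussians map (floored at a small
  positive constant so the minimum contract is never violated), chi terms use
  one harmonic constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import ForceFieldParams, load_forcefield_params
from .constants import MAIN_CHAIN_ATOMS
from .structure_io import ChainModel
from .topology import SoftDihedral, Topology

#: Ratio of the LJ inflection radius to sigma: d2/dr2 of 4e[(s/r)^12-(s/r)^6]
#: vanishes at r = (26/7)^(1/6) sigma, independent of epsilon.
LJ_INFLECTION_FACTOR = (26.0 / 7.0) ** (1.0 / 6.0)


def lj_inflection_cutoff(sigma_ij: float) -> float:
    """Radius of the inflection point of the LJ 6-12 curve for pair sigma."""
    if sigma_ij <= 0:
        raise ValueError(f"sigma must be positive, got {sigma_ij}")
    return LJ_INFLECTION_FACTOR * sigma_ij


@dataclass(frozen=True)
class NbiTerm:
    atom_i: int
    atom_j: int
    rest_length: float
    stiffness: float
    klass: str  # MC_MC | MC_SC | SC_SC


@dataclass(frozen=True)
class TorsionTerm:
    dihedral: SoftDihedral
    rest_angle: float  # degrees, the deposited value
    stiffness: float  # kcal/mol/rad^2
    origin: str  # phipsi_map | chi_harmonic


@dataclass
class SpringSystem:
    nbi: list[NbiTerm]
    torsional: list[TorsionTerm]
    params: ForceFieldParams

    def nbi_class_counts(self) -> dict[str, int]:
        counts = {"MC_MC": 0, "MC_SC": 0, "SC_SC": 0}
        for t in self.nbi:
            counts[t.klass] += 1
        return counts


def _lj_curvature_at(r: float, sigma: float, epsilon: float) -> float:
    """|V''(r)| of the 6-12 potential, used by the curvature-weighted profile."""
    sr6 = (sigma / r) ** 6
    v2 = 4.0 * epsilon * (156.0 * sr6 * sr6 - 42.0 * sr6) / r**2
    return abs(v2)


def nbi_stiffness(rest_length: float, sigma: float, epsilon: float,
                  params: ForceFieldParams) -> float:
    """Distance-spring constant for one NBI (kcal/mol/Å^2), strictly positive
    and non-increasing in the rest length inside the cutoff."""
    cutoff = lj_inflection_cutoff(sigma)
    if rest_length >= cutoff:
        raise ValueError(
            f"rest length {rest_length:.3f} Å at or beyond cutoff {cutoff:.3f} Å"
        )
    if params.nbi_profile == "constant":
        base = params.nbi_k
    elif params.nbi_profile == "lj_curvature":
        # monotone: clamp below r_min so the repulsive rise is not amplified
        r_eval = max(rest_length, 2.0 ** (1.0 / 6.0) * sigma)
        base = max(_lj_curvature_at(r_eval, sigma, epsilon), 1e-6)
    else:
        raise ValueError(f"unknown NBI profile {params.nbi_profile!r}")
    return params.global_scale * base


def detect_nbi(chain: ChainModel, topology: Topology,
               params: ForceFieldParams | None = None) -> list[NbiTerm]:
    """All atom pairs >3 bonds apart and strictly inside the pairwise
    inflection-point cutoff, classified main-chain/side-chain, ordered i<j."""
    params = params or load_forcefield_params()
    coords = chain.coords
    elements = [a.element for a in chain.atoms]
    for a in chain.atoms:
        if a.element not in params.lj_sigma:
            raise KeyError(
                f"no LJ class for atom {a.name} ({a.element}) in residue "
                f"{a.residue_name} {a.residue_index}"
            )
    max_sigma = max(params.lj_sigma[e] for e in set(elements))
    max_cutoff = lj_inflection_cutoff(max_sigma)

    near = topology.neighbors_within(3)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=max_cutoff, output_type="ndarray")

    is_mc = [a.name in MAIN_CHAIN_ATOMS for a in chain.atoms]
    terms: list[NbiTerm] = []
    for i, j in pairs:
        i, j = int(min(i, j)), int(max(i, j))
        if j in near[i]:
            continue  # separation <= 3 bonds
        sigma = params.sigma_pair(elements[i], elements[j])
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d >= lj_inflection_cutoff(sigma):
            continue
        if is_mc[i] and is_mc[j]:
            klass = "MC_MC"
        elif is_mc[i] or is_mc[j]:
            klass = "MC_SC"
        else:
            klass = "SC_SC"
        k = nbi_stiffness(d, sigma, params.epsilon_pair(elements[i], elements[j]), params)
        terms.append(NbiTerm(i, j, d, k, klass))
    terms.sort(key=lambda t: (t.atom_i, t.atom_j))
    return terms


def phipsi_map_energy(phi: float, psi: float, params: ForceFieldParams) -> float:
    """Ramachandran-style map E(phi, psi), degrees in, kcal/mol out."""
    e = 0.0
    for w in params.phipsi_wells:
        dphi = _angdiff(phi, w.phi)
        dpsi = _angdiff(psi, w.psi)
        e -= w.depth * math.exp(-(dphi**2 + dpsi**2) / w.width**2)
    return e


def _angdiff(a: float, b: float) -> float:
    d = (a - b) % 360.0
    return d - 360.0 if d > 180.0 else d


def phipsi_curvature(phi: float, psi: float, params: ForceFieldParams,
                     which: str) -> float:
    """Second derivative of the map along phi or psi (kcal/mol/rad^2)."""
    total = 0.0
    deg2rad = 180.0 / math.pi
    for w in params.phipsi_wells:
        dphi = _angdiff(phi, w.phi)
        dpsi = _angdiff(psi, w.psi)
        g = math.exp(-(dphi**2 + dpsi**2) / w.width**2)
        d = dphi if which == "phi" else dpsi
        # d2/dx2 of -A exp(-((x-x0)^2+...)/w^2) = A g (2/w^2)(1 - 2 d^2/w^2)
        cur_deg2 = w.depth * g * (2.0 / w.width**2) * (1.0 - 2.0 * d**2 / w.width**2)
        total += cur_deg2 * deg2rad**2
    return total


def torsional_stiffness(soft: SoftDihedral, params: ForceFieldParams,
                        phi_psi: tuple[float, float] | None = None) -> TorsionTerm:
    """Spring constant for one soft dihedral at the deposited geometry.

    phi/psi terms take the map curvature at the residue's (phi, psi), floored
    at ``curvature_floor``; chi terms take the configured harmonic constant.
    """
    if soft.kind == "chi":
        return TorsionTerm(soft, soft.value, params.k_chi, "chi_harmonic")
    phi, psi = phi_psi if phi_psi is not None else (soft.value, soft.value)
    cur = phipsi_curvature(phi, psi, params, soft.kind)
    return TorsionTerm(soft, soft.value, max(params.curvature_floor, cur), "phipsi_map")


def build_springs(chain: ChainModel, topology: Topology,
                  params: ForceFieldParams | None = None) -> SpringSystem:
    """Assemble the complete Hookean term set about the deposited geometry."""
    params = params or load_forcefield_params()
    nbi = detect_nbi(chain, topology, params)
    # residue -> (phi, psi) for map-curvature evaluation (missing -> 0 deg)
    phi_psi: dict[int, list[float]] = {}
    for sd in topology.soft_dihedrals:
        if sd.kind in ("phi", "psi"):
            pair = phi_psi.setdefault(sd.residue_index, [0.0, 0.0])
            pair[0 if sd.kind == "phi" else 1] = sd.value
    torsional = [
        torsional_stiffness(
            sd, params,
            tuple(phi_psi.get(sd.residue_index, [0.0, 0.0])) if sd.kind != "chi" else None,
        )
        for sd in topology.soft_dihedrals
    ]
    return SpringSystem(nbi=nbi, torsional=torsional, params=params)
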