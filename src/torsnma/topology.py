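"""Covalent topology and the soft torsional degrees of freedom.

The covalent bond graph is built from the residue template table: intra-residue
bonds per template, peptide bonds between consecutive residues of the same
resolved range, OXT attached to the terminal carbonyl carbon, and disulfides
whenever two SG atoms sit closer than 2.5 Å.  From the graph we enumerate

* bonds, all-pairs bond angles, and all proper torsion paths (bookkeeping);
* the *soft* dihedrals -- the only mobile degrees of freedom of the model:
  backbone phi/psi plus side-chain chi torsions.  Omega (peptide) torsions,
  ring-internal torsions, proline phi, and torsions of rigid plates (aromatic
  rings, guanidinium, carboxylate, amide) are frozen.  Psi of the C-terminal
  residue is defined through OXT so that every residue carries a psi.

Because bond lengths and angles are frozen, the degrees-of-freedom ledger of a
chain with N atoms reads 3N - 6 = |bonds| + |angles| + dihedral_dof, which
defines the reported ``dihedral_dof`` remainder (the enumerated proper-torsion
paths are redundant where the graph branches).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .config import load_residue_templates
from .geometry import dihedral
from .structure_io import ChainModel

DISULFIDE_CUTOFF = 2.5  # Å between SG atoms

_KIND_ORDER = {"phi": 0, "psi": 1, "chi": 2}


@dataclass(frozen=True)
class SoftDihedral:
    """A mobile torsion: kind phi/psi/chi, its atom quadruple and rotor set."""

    kind: str
    atom_quad: tuple[int, int, int, int]
    residue_index: int
    chi_level: int
    value: float  # degrees at the reference (PDB) geometry
    rotor: frozenset[int] = field(default=frozenset(), compare=False)


@dataclass
class Topology:
    """Enumerated covalent structure of one chain."""

    n_atoms: int
    bonds: list[tuple[int, int]]
    angles: list[tuple[int, int, int]]
    dihedrals: list[tuple[int, int, int, int]]
    soft_dihedrals: list[SoftDihedral] = field(default_factory=list)
    adjacency: list[list[int]] = field(default_factory=list)

    @property
    def dihedral_dof(self) -> int:
        """Torsional DOF remainder: 3N - 6 - |bonds| - |angles|."""
        return 3 * self.n_atoms - 6 - len(self.bonds) - len(self.angles)

    def soft_counts(self) -> dict[str, int]:
        counts = {"phi": 0, "psi": 0, "chi": 0}
        for sd in self.soft_dihedrals:
            counts[sd.kind] += 1
        counts["total"] = len(self.soft_dihedrals)
        return counts

    def bond_separation(self, i: int, j: int) -> float:
        """Minimal number of covalent bonds between atoms i and j (BFS);
        +inf if they are in different connected components."""
        n = self.n_atoms
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"atom index out of range: {i}, {j}")
        if i == j:
            return 0
        dist = {i: 0}
        queue = deque([i])
        while queue:
            u = queue.popleft()
            for v in self.adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    if v == j:
                        return dist[v]
                    queue.append(v)
        return math.inf

    def neighbors_within(self, k: int) -> list[set[int]]:
        """For every atom, the set of atoms within k bonds (excluding itself)."""
        out: list[set[int]] = []
        for i in range(self.n_atoms):
            dist = {i: 0}
            queue = deque([i])
            while queue:
                u = queue.popleft()
                if dist[u] == k:
                    continue
                for v in self.adjacency[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        queue.append(v)
            dist.pop(i)
            out.append(set(dist))
        return out


def _rotor_component(adjacency: list[list[int]], b: int, c: int) -> frozenset[int]:
    """Connected component containing c after deleting bond (b, c).

    Raises if b remains reachable (the bond closes a ring, so the torsion is
    not free)."""
    seen = {c}
    queue = deque([c])
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if u == c and v == b:
                continue
            if v == b:
                raise ValueError("central bond lies in a ring; torsion is not free")
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return frozenset(seen)


def build_topology(chain: ChainModel, templates: dict | None = None) -> Topology:
    """Enumerate bonds, angles and torsion paths for a chain model."""
    tpl = templates or load_residue_templates()
    residues_tpl = tpl["residues"]

    index: dict[tuple[int, str], int] = {
        (a.residue_index, a.name): i for i, a in enumerate(chain.atoms)
    }
    bonds: set[tuple[int, int]] = set()

    def add_bond(i: int, j: int) -> None:
        bonds.add((i, j) if i < j else (j, i))

    range_of: dict[int, int] = {}
    for k, (lo, hi) in enumerate(chain.resolved_ranges):
        for r in range(lo, hi + 1):
            range_of[r] = k

    backbone_bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    for res_index, res_name, sl in chain.residues:
        if res_name not in residues_tpl:
            raise ValueError(f"unknown residue {res_name} {res_index}: no template")
        entry = residues_tpl[res_name]
        present = {a.name for a in chain.atoms[sl]}
        for pair in backbone_bonds + [tuple(b) for b in entry["bonds"]]:
            a_name, b_name = pair
            ia = index.get((res_index, a_name))
            ib = index.get((res_index, b_name))
            if ia is None or ib is None:
                missing = a_name if ia is None else b_name
                raise ValueError(
                    f"residue {res_name} {res_index} missing template atom {missing}"
                )
            add_bond(ia, ib)
        if "OXT" in present:
            add_bond(index[(res_index, "C")], index[(res_index, "OXT")])

    # peptide bonds within each resolved range
    for (r1, _, _), (r2, _, _) in zip(chain.residues, chain.residues[1:]):
        if r2 == r1 + 1 and range_of.get(r1) == range_of.get(r2):
            add_bond(index[(r1, "C")], index[(r2, "N")])

    # disulfides
    sg = [(i, np.array(a.coords)) for i, a in enumerate(chain.atoms) if a.name == "SG"]
    for k in range(len(sg)):
        for l in range(k + 1, len(sg)):
            if np.linalg.norm(sg[k][1] - sg[l][1]) < DISULFIDE_CUTOFF:
                add_bond(sg[k][0], sg[l][0])

    n = len(chain.atoms)
    adjacency: list[list[int]] = [[] for _ in range(n)]
    for i, j in sorted(bonds):
        adjacency[i].append(j)
        adjacency[j].append(i)

    angles = [
        (i, j, k)
        for j in range(n)
        for ai, i in enumerate(adjacency[j])
        for k in adjacency[j][ai + 1:]
    ]
    dihedrals = []
    for j, k in sorted(bonds):
        for i in adjacency[j]:
            if i == k:
                continue
            for l in adjacency[k]:
                if l == j or l == i:
                    continue
                dihedrals.append((i, j, k, l))

    topo = Topology(
        n_atoms=n,
        bonds=sorted(bonds),
        angles=sorted(angles),
        dihedrals=sorted(dihedrals),
        adjacency=adjacency,
    )
    topo.soft_dihedrals = classify_soft_dihedrals(topo, chain, tpl)
    return topo


def classify_soft_dihedrals(
    topology: Topology, chain: ChainModel, templates: dict | None = None
) -> list[SoftDihedral]:
    """Enumerate the mobile phi/psi/chi torsions with their rotor sets."""
    tpl = templates or load_residue_templates()
    residues_tpl = tpl["residues"]
    index = {(a.residue_index, a.name): i for i, a in enumerate(chain.atoms)}
    coords = chain.coords
    range_of: dict[int, int] = {}
    for k, (lo, hi) in enumerate(chain.resolved_ranges):
        for r in range(lo, hi + 1):
            range_of[r] = k

    def measured(quad: tuple[int, int, int, int]) -> float:
        a, b, c, d = quad
        return math.degrees(dihedral(coords[a], coords[b], coords[c], coords[d]))

    out: list[SoftDihedral] = []
    resolved = {r for r, _, _ in chain.residues}
    for res_index, res_name, _sl in chain.residues:
        entry = residues_tpl[res_name]
        # phi: (C_{i-1}, N_i, CA_i, C_i); absent at range starts and for Pro
        if (
            entry.get("phi_soft", True)
            and res_index - 1 in resolved
            and range_of.get(res_index - 1) == range_of.get(res_index)
        ):
            quad = (
                index[(res_index - 1, "C")],
                index[(res_index, "N")],
                index[(res_index, "CA")],
                index[(res_index, "C")],
            )
            try:  # a disulfide loop puts backbone bonds inside a ring: frozen
                rotor = _rotor_component(topology.adjacency, quad[1], quad[2])
            except ValueError:
                rotor = None
            if rotor is not None:
                out.append(SoftDihedral("phi", quad, res_index, 0, measured(quad), rotor))
        # psi: (N_i, CA_i, C_i, N_{i+1}) or the OXT variant at the C terminus
        fourth = None
        if (
            res_index + 1 in resolved
            and range_of.get(res_index + 1) == range_of.get(res_index)
        ):
            fourth = index[(res_index + 1, "N")]
        elif (res_index, "OXT") in index:
            fourth = index[(res_index, "OXT")]
        if fourth is not None:
            quad = (
                index[(res_index, "N")],
                index[(res_index, "CA")],
                index[(res_index, "C")],
                fourth,
            )
            try:
                rotor = _rotor_component(topology.adjacency, quad[1], quad[2])
            except ValueError:
                rotor = None
            if rotor is not None:
                out.append(SoftDihedral("psi", quad, res_index, 0, measured(quad), rotor))
        # chi torsions from the template table
        for level, names in enumerate(entry.get("chi", []), start=1):
            try:
                quad = tuple(index[(res_index, nm)] for nm in names)
            except KeyError:
                continue  # atom unresolved in this structure
            try:
                rotor = _rotor_component(topology.adjacency, quad[1], quad[2])
            except ValueError:
                continue  # inside a ring (e.g. a disulfide loop): frozen
            out.append(SoftDihedral("chi", quad, res_index, level, measured(quad), rotor))

    out.sort(key=lambda sd: (sd.residue_index, _KIND_ORDER[sd.kind], sd.chi_level))
    return out
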