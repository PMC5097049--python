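"""Self-contained test-structure generators.

Builds heavy-atom polypeptides from internal coordinates (ideal covalent
geometry from the residue template table, user-controlled phi/psi/chi), a
two-helix "dumbbell" with a flexible glycine hinge emulating multi-domain
architecture, and exact torsional perturbations that create conformer pairs
with known ground-truth displacements.  All generators are pure functions of
their specification and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import load_residue_templates
from .constants import element_of
from .geometry import place_atom
from .structure_io import AtomRecord, ChainModel
from .topology import Topology

_ONE_TO_THREE: dict[str, str] | None = None


def _one_to_three() -> dict[str, str]:
    global _ONE_TO_THREE
    if _ONE_TO_THREE is None:
        tpl = load_residue_templates()
        _ONE_TO_THREE = {v["letter"]: k for k, v in tpl["residues"].items()}
    return _ONE_TO_THREE


@dataclass(frozen=True)
class PeptideSpec:
    """Specification of a synthetic peptide.

    ``phi_psi`` is one (phi, psi) pair per residue, degrees; phi of the first
    residue is ignored (undefined).  ``chi`` optionally lists per-residue chi
    values; missing entries use the template defaults.  ``seed`` controls the
    optional Gaussian coordinate jitter of amplitude ``jitter`` (Å).
    """

    sequence: str
    phi_psi: tuple[tuple[float, float], ...]
    chi: tuple[tuple[float, ...], ...] | None = None
    seed: int = 0
    jitter: float = 0.0
    chain_id: str = "S"
    with_oxt: bool = True

    def __post_init__(self) -> None:
        if len(self.phi_psi) != len(self.sequence):
            raise ValueError("phi_psi length must match sequence length")
        if self.chi is not None and len(self.chi) != len(self.sequence):
            raise ValueError("chi length must match sequence length")


def build_peptide(spec: PeptideSpec, templates: dict | None = None) -> ChainModel:
    """Build a heavy-atom chain from internal coordinates (NeRF chain
    extension).  Measuring phi/psi on the output returns the spec values to
    well below 1e-6 degrees."""
    tpl = templates or load_residue_templates()
    geo = tpl["backbone"]["geometry"]
    default_chi = tpl.get("default_chi", [-65.0, 180.0, 180.0, 180.0])
    three = _one_to_three()

    rad = math.radians
    n_res = len(spec.sequence)
    atoms: list[AtomRecord] = []
    positions: dict[tuple[int, str], np.ndarray] = {}

    def add(res_i: int, res_name: str, name: str, xyz: np.ndarray) -> None:
        positions[(res_i, name)] = xyz
        atoms.append(
            AtomRecord(
                serial=len(atoms) + 1,
                name=name,
                element=element_of(name),
                alt_loc="",
                occupancy=1.0,
                coords=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                b_exp=0.0,
                residue_index=res_i,
                residue_name=res_name,
                chain_id=spec.chain_id,
            )
        )

    for i, letter in enumerate(spec.sequence, start=1):
        try:
            res_name = three[letter]
        except KeyError:
            raise ValueError(f"unknown residue letter {letter!r}") from None
        phi, psi = spec.phi_psi[i - 1]
        if i == 1:
            n = np.zeros(3)
            ca = np.array([geo["n_ca"], 0.0, 0.0])
            ang = rad(geo["n_ca_c"])
            c = ca + geo["ca_c"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
            add(i, res_name, "N", n)
            add(i, res_name, "CA", ca)
            add(i, res_name, "C", c)
        else:
            prev_n = positions[(i - 1, "N")]
            prev_ca = positions[(i - 1, "CA")]
            prev_c = positions[(i - 1, "C")]
            prev_psi = rad(spec.phi_psi[i - 2][1])
            n = place_atom(prev_n, prev_ca, prev_c, geo["c_n"], rad(geo["ca_c_n"]), prev_psi)
            ca = place_atom(prev_ca, prev_c, n, geo["n_ca"], rad(geo["c_n_ca"]), rad(geo["omega"]))
            c = place_atom(prev_c, n, ca, geo["ca_c"], rad(geo["n_ca_c"]), rad(phi))
            add(i, res_name, "N", n)
            add(i, res_name, "CA", ca)
            add(i, res_name, "C", c)
        # carbonyl O anti to the next amide nitrogen (or to OXT)
        o = place_atom(
            positions[(i, "N")], positions[(i, "CA")], positions[(i, "C")],
            geo["c_o"], rad(geo["ca_c_o"]), rad(psi + 180.0),
        )
        add(i, res_name, "O", o)
        # side chain per template recipe
        chis = None
        if spec.chi is not None:
            chis = spec.chi[i - 1]
        for entry in tpl["residues"][res_name]["build"]:
            refs = [positions[(i, r)] for r in entry["refs"]]
            tors_spec = entry["torsion"]
            if "cb" in tors_spec:
                tors = geo["cb_torsion"]
            elif "fixed" in tors_spec:
                tors = tors_spec["fixed"]
            else:
                k = tors_spec["chi"]
                base = (
                    chis[k - 1]
                    if chis is not None and len(chis) >= k
                    else default_chi[k - 1]
                )
                tors = base + tors_spec.get("offset", 0.0)
            xyz = place_atom(refs[0], refs[1], refs[2], entry["bond"], rad(entry["angle"]), rad(tors))
            add(i, res_name, entry["atom"], xyz)
        if i == n_res and spec.with_oxt:
            oxt = place_atom(
                positions[(i, "N")], positions[(i, "CA")], positions[(i, "C")],
                geo["c_oxt"], rad(geo["ca_c_oxt"]), rad(psi),
            )
            add(i, res_name, "OXT", oxt)

    chain = ChainModel(chain_id=spec.chain_id, atoms=atoms,
                       source_id=f"synthetic:{spec.sequence}:{spec.seed}")
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        chain = chain.with_coords(
            chain.coords + rng.normal(0.0, spec.jitter, size=(len(atoms), 3))
        )
    return chain


HELIX_PHI_PSI = (-57.0, -47.0)
EXTENDED_PHI_PSI = (-139.0, 135.0)


def build_dumbbell(helix_len: int = 10, linker: int = 3, seed: int = 0) -> ChainModel:
    """Two ideal poly-alanine helices joined by an extended glycine linker.

    The hinge-like linker makes the slowest mode an inter-domain bending
    motion, emulating the head/torso/foot inter-domain mobility of a
    multi-domain subunit.
    """
    if helix_len < 6:
        raise ValueError("helix_len must be >= 6")
    if linker < 2:
        raise ValueError("linker must be >= 2 glycines")
    seq = "A" * helix_len + "G" * linker + "A" * helix_len
    phi_psi = (
        [HELIX_PHI_PSI] * helix_len
        + [EXTENDED_PHI_PSI] * linker
        + [HELIX_PHI_PSI] * helix_len
    )
    return build_peptide(
        PeptideSpec(sequence=seq, phi_psi=tuple(phi_psi), seed=seed, chain_id="S")
    )


def perturb_along_torsions(
    chain: ChainModel,
    topology: Topology,
    deltas: np.ndarray,
    seed: int = 0,
    noise: float = 0.0,
) -> ChainModel:
    """Exact internal-coordinate perturbation: rotate every soft dihedral j by
    ``deltas[j]`` radians about its own bond axis (rotor-set atoms only).

    Bond lengths and angles are preserved exactly; optional Gaussian torsional
    noise of standard deviation ``noise`` radians is controlled by ``seed``.
    """
    from .geometry import rotation_about_axis  # local import to avoid cycle noise

    deltas = np.asarray(deltas, dtype=float)
    if deltas.shape != (len(topology.soft_dihedrals),):
        raise ValueError("deltas must have one entry per soft dihedral")
    if not np.all(np.isfinite(deltas)):
        raise ValueError("deltas must be finite")
    if noise > 0:
        rng = np.random.default_rng(seed)
        deltas = deltas + rng.normal(0.0, noise, size=deltas.shape)

    coords = chain.coords
    for sd, delta in zip(topology.soft_dihedrals, deltas):
        if delta == 0.0:
            continue
        _, b, c, _ = sd.atom_quad
        axis = coords[c] - coords[b]
        R = rotation_about_axis(axis, float(delta))
        rotor = sorted(sd.rotor)
        coords[rotor] = (coords[rotor] - coords[c]) @ R.T + coords[c]
    return chain.with_coords(coords)
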