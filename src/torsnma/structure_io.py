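"""Validated heavy-atom chain models from PDB files.

A :class:`ChainModel` is the ordered heavy-atom representation of a single
polypeptide chain: coordinates, experimental B-factors, residue identity, and
the resolved residue-index ranges (gaps between deposited segments are kept
explicit so downstream topology never bonds across a gap).  Hydrogens and
HETATM records are excluded; alternate locations are collapsed to a single
conformation by a deterministic policy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import gemmi
import numpy as np

from .config import load_residue_templates
from .constants import ATOMIC_MASS, element_of
from .geometry import kabsch

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a deposited or generated chain."""

    serial: int
    name: str
    element: str
    alt_loc: str
    occupancy: float
    coords: tuple[float, float, float]
    b_exp: float
    residue_index: int
    residue_name: str
    chain_id: str

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.b_exp < 0:
            raise ValueError(f"negative B-factor for atom {self.name}")
        if not (0.0 < self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside (0, 1] for {self.name}")


@dataclass
class ChainModel:
    """Ordered heavy-atom model of one chain (hydrogens excluded)."""

    chain_id: str
    atoms: list[AtomRecord]
    source_id: str = ""
    # (residue_index, residue_name, slice into atoms), in chain order
    residues: list[tuple[int, str, slice]] = field(default_factory=list)
    resolved_ranges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residues:
            self._index_residues()
        seen: set[tuple[str, int, str, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_index, a.name, "")
            if key in seen:
                raise ValueError(
                    f"duplicate atom {a.name} in residue {a.residue_index} after "
                    "alt-loc resolution"
                )
            seen.add(key)

    def _index_residues(self) -> None:
        residues: list[tuple[int, str, slice]] = []
        start = 0
        for i, a in enumerate(self.atoms):
            if i > 0 and a.residue_index != self.atoms[i - 1].residue_index:
                prev = self.atoms[start]
                residues.append((prev.residue_index, prev.residue_name, slice(start, i)))
                start = i
        if self.atoms:
            prev = self.atoms[start]
            residues.append((prev.residue_index, prev.residue_name, slice(start, len(self.atoms))))
        self.residues = residues
        if not self.resolved_ranges:
            self.resolved_ranges = self._contiguous_ranges()
        for lo, hi in self.resolved_ranges:
            idxs = [r for r, _, _ in residues if lo <= r <= hi]
            if idxs != sorted(set(idxs)):
                raise ValueError("residue indices not strictly increasing within a range")

    def _contiguous_ranges(self) -> list[tuple[int, int]]:
        ranges: list[tuple[int, int]] = []
        for r, _, _ in self.residues:
            if ranges and r == ranges[-1][1] + 1:
                ranges[-1] = (ranges[-1][0], r)
            else:
                ranges.append((r, r))
        return ranges

    # -- array views ------------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASS[a.element] for a in self.atoms], dtype=float)

    @property
    def b_exp(self) -> np.ndarray:
        return np.array([a.b_exp for a in self.atoms], dtype=float)

    def atom_index(self, residue_index: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.residue_index == residue_index and a.name == name:
                return i
        raise KeyError(f"atom {name} of residue {residue_index} not in chain {self.chain_id}")

    def ca_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.name == "CA"]

    def with_coords(self, coords: np.ndarray) -> "ChainModel":
        """Copy of this chain with replaced coordinates (same atoms/order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            dataclasses.replace(a, coords=tuple(float(x) for x in xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return ChainModel(
            chain_id=self.chain_id,
            atoms=atoms,
            source_id=self.source_id,
            residues=list(self.residues),
            resolved_ranges=list(self.resolved_ranges),
        )


class ChainNotFoundError(KeyError):
    pass


def read_pdb_chain(
    path: str | Path,
    chain_id: str,
    altloc_policy: str = "highest_occupancy",
    nonstandard: str = "error",
) -> ChainModel:
    """Read one protein chain from a PDB file into a heavy-atom model.

    HETATM records (nucleotide, cation, water) are excluded.  Alt-locs are
    collapsed per ``altloc_policy`` ("highest_occupancy": larger occupancy
    wins, ties broken by alt-loc label order; "label_A": blank or 'A' wins).
    Missing residues remain as gaps between ``resolved_ranges``.
    """
    if altloc_policy not in {"highest_occupancy", "label_A"}:
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    model = st[0]
    names = [ch.name for ch in model]
    if chain_id not in names:
        raise ChainNotFoundError(
            f"chain {chain_id!r} not in {path}; available chains: {sorted(set(names))}"
        )
    atoms: list[AtomRecord] = []
    serial = 0
    for ch in model:
        if ch.name != chain_id:
            continue
        for res in ch:
            if res.het_flag == "H":
                continue
            if res.name not in _STANDARD_RESIDUES:
                if nonstandard == "error":
                    raise ValueError(
                        f"nonstandard residue {res.name} {res.seqid.num} in chain "
                        f"{chain_id}; supply a mapping table to accept it"
                    )
                continue
            if res.seqid.icode not in (" ", ""):
                raise ValueError(
                    f"insertion code {res.seqid.icode!r} at residue {res.seqid.num} "
                    "is not supported"
                )
            # collapse alt-locs per policy, keep file order otherwise
            chosen: dict[str, gemmi.Atom] = {}
            for at in res:
                if at.element.name == "H" or at.element.name == "D":
                    continue
                prev = chosen.get(at.name)
                if prev is None:
                    chosen[at.name] = at
                    continue
                if altloc_policy == "highest_occupancy":
                    if (at.occ, -ord(at.altloc or "z")) > (prev.occ, -ord(prev.altloc or "z")):
                        chosen[at.name] = at
                else:  # label_A
                    if (prev.altloc or " ") not in (" ", "A") and (at.altloc or " ") in (" ", "A"):
                        chosen[at.name] = at
            for at in chosen.values():
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=at.name,
                        element=at.element.name.upper(),
                        alt_loc="",
                        occupancy=min(max(at.occ, 1e-6), 1.0),
                        coords=(at.pos.x, at.pos.y, at.pos.z),
                        b_exp=max(at.b_iso, 0.0),
                        residue_index=res.seqid.num,
                        residue_name=res.name,
                        chain_id=chain_id,
                    )
                )
    return ChainModel(chain_id=chain_id, atoms=atoms, source_id=f"{Path(path).stem}:{chain_id}")


def write_pdb(chain_or_chains: ChainModel | Sequence[ChainModel], path: str | Path) -> None:
    """Write chains as standard ATOM records (wwPDB v3.3 columns)."""
    chains = [chain_or_chains] if isinstance(chain_or_chains, ChainModel) else list(chain_or_chains)
    lines: list[str] = []
    serial = 0
    for chain in chains:
        for a in chain.atoms:
            serial += 1
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{a.residue_name:>3s} "
                f"{chain.chain_id:1s}{a.residue_index:4d}    "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{a.b_exp:6.2f}          {a.element:>2s}"
            )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _paired_indices(
    mobile: ChainModel,
    target: ChainModel,
    selection: Callable[[AtomRecord], bool] | None,
    alignment: dict[int, int] | None = None,
) -> tuple[list[int], list[int]]:
    """Pair atoms by (residue_index, name), optionally via a residue alignment
    map (mobile residue index -> target residue index)."""
    sel = selection or (lambda a: True)
    tgt_lookup = {
        (a.residue_index, a.name): i for i, a in enumerate(target.atoms) if sel(a)
    }
    mi: list[int] = []
    ti: list[int] = []
    for i, a in enumerate(mobile.atoms):
        if not sel(a):
            continue
        tgt_res = alignment.get(a.residue_index) if alignment else a.residue_index
        if tgt_res is None:
            continue
        j = tgt_lookup.get((tgt_res, a.name))
        if j is not None:
            mi.append(i)
            ti.append(j)
    return mi, ti


def superpose(
    mobile: ChainModel,
    target: ChainModel,
    selection: Callable[[AtomRecord], bool] | None = None,
    alignment: dict[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of paired atoms.

    Pairing is by (residue_index, atom name), or through an explicit residue
    ``alignment`` map for chains with different numbering.  Returns
    (rotation, translation, rmsd); rotation is proper (det +1).
    """
    mi, ti = _paired_indices(mobile, target, selection, alignment)
    if len(mi) < 3:
        raise ValueError(f"superposition needs >= 3 paired atoms, got {len(mi)}")
    return kabsch(mobile.coords[mi], target.coords[ti])


def transform(chain: ChainModel, rotation: np.ndarray, translation: np.ndarray) -> ChainModel:
    return chain.with_coords(chain.coords @ np.asarray(rotation).T + np.asarray(translation))


def reconstruct_gap(
    target: ChainModel,
    donor: ChainModel,
    gap: tuple[int, int],
    flank: int = 4,
) -> ChainModel:
    """Fill a missing residue interval by rigid-body transfer from a donor.

    The donor's gap residues are transformed by the Kabsch superposition of
    ``flank`` anchor residues on each side of the gap (all shared heavy atoms)
    and inserted; every atom outside the gap is untouched.
    """
    lo, hi = gap
    if hi < lo:
        return target
    target_res = {r for r, _, _ in target.residues}
    donor_res = {r for r, _, _ in donor.residues}
    missing_in_donor = [r for r in range(lo, hi + 1) if r not in donor_res]
    if missing_in_donor:
        raise ValueError(f"donor also missing gap residues {missing_in_donor}")
    if not [r for r in range(lo, hi + 1) if r not in target_res]:
        return target  # nothing to rebuild
    anchors = [r for r in range(lo - flank, lo)] + [r for r in range(hi + 1, hi + 1 + flank)]
    unresolved = [r for r in anchors if r not in target_res or r not in donor_res]
    if unresolved:
        raise ValueError(f"flank residues {unresolved} unresolved in target or donor")

    anchor_set = set(anchors)
    sel = lambda a: a.residue_index in anchor_set  # noqa: E731
    R, t, _ = superpose(donor, target, selection=sel)

    inserted = []
    for a in donor.atoms:
        if lo <= a.residue_index <= hi:
            xyz = np.array(a.coords) @ R.T + t
            inserted.append(
                dataclasses.replace(
                    a, chain_id=target.chain_id, coords=tuple(float(x) for x in xyz)
                )
            )
    merged = [a for a in target.atoms if a.residue_index < lo]
    merged += inserted
    merged += [a for a in target.atoms if a.residue_index > hi]
    merged = [dataclasses.replace(a, serial=i + 1) for i, a in enumerate(merged)]
    return ChainModel(
        chain_id=target.chain_id,
        atoms=merged,
        source_id=f"{target.source_id}+gap{lo}-{hi}from{donor.source_id}",
    )


def validate_against_templates(chain: ChainModel, templates: dict | None = None) -> None:
    """Check every residue against the template table (unknown residue or
    missing/extra heavy atoms raise)."""
    tpl = templates or load_residue_templates()
    backbone = set(tpl["backbone"]["atoms"])
    for res_index, res_name, sl in chain.residues:
        if res_name not in tpl["residues"]:
            raise ValueError(f"no template for residue {res_name} {res_index}")
        expected = backbone | set(tpl["residues"][res_name]["atoms"])
        present = {a.name for a in chain.atoms[sl]}
        missing = expected - present
        extra = present - expected - {"OXT"}
        if missing:
            raise ValueError(f"residue {res_name} {res_index} missing atoms {sorted(missing)}")
        if extra:
            raise ValueError(f"residue {res_name} {res_index} has unexpected atoms {sorted(extra)}")
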