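"""Region-based motility reports.

Encodes the anatomical region lexicon of the F1-ATPase subunits (head, torso,
foot, arm, fist, shoulder, lid, strut, posterior surface, P-loop) as editable
residue-interval data, and derives the region reports: caliper distances under
mode activation, boundary-crossing NBI counts, and residue tallies.  Reports
always carry the intervals actually used.
"""

from __future__ import annotations

import numpy as np

from .config import load_region_map
from .constants import KB_KCAL_MOL_K
from .forcefield import SpringSystem
from .morph import apply_mode_displacement
from .nma_engine import ChainAnalysis
from .structure_io import ChainModel


class RegionMap:
    """Named regions -> residue-interval sets, per subunit type."""

    def __init__(self, data: dict[str, dict[str, list[list[int]]]] | None = None):
        self.data = data or load_region_map()
        for scheme, regions in self.data.items():
            for name, intervals in regions.items():
                for lo, hi in intervals:
                    if hi < lo:
                        raise ValueError(
                            f"invalid interval {lo}-{hi} in {scheme}/{name}"
                        )

    def intervals(self, scheme: str, region: str) -> list[tuple[int, int]]:
        try:
            return [tuple(iv) for iv in self.data[scheme][region]]
        except KeyError:
            raise KeyError(f"no region {region!r} in scheme {scheme!r}") from None

    def residues(self, scheme: str, region: str) -> set[int]:
        out: set[int] = set()
        for lo, hi in self.intervals(scheme, region):
            out.update(range(lo, hi + 1))
        return out


def caliper_distance(
    analysis: ChainAnalysis,
    mode_index: int,
    temperature: float,
    atom_a: tuple[int, str],
    atom_b: tuple[int, str],
    n_phases: int = 16,
) -> tuple[float, float]:
    """Distance between two atoms tracked over one full mode oscillation.

    The chain is deformed along mode ``mode_index`` (1-based) at amplitude
    a(t) = A cos(2 pi t), with A the peak thermal amplitude sqrt(2 k_B T)/omega.
    Returns (cycle mean, half peak-to-peak excursion) in Å.
    """
    chain = analysis.chain
    modes = analysis.modes
    ia = chain.atom_index(*atom_a)
    ib = chain.atom_index(*atom_b)
    lam = modes.eigenvalues[mode_index - 1]
    peak = float(np.sqrt(2.0 * KB_KCAL_MOL_K * temperature / lam)) if temperature > 0 else 0.0
    amps = peak * np.cos(2.0 * np.pi * np.arange(n_phases) / n_phases)
    dists = []
    for a in amps:
        amp_vec = np.zeros(mode_index)
        amp_vec[-1] = a
        deformed = apply_mode_displacement(chain, analysis.topology, modes, amp_vec)
        c = deformed.coords
        dists.append(float(np.linalg.norm(c[ia] - c[ib])))
    dists = np.array(dists)
    return float(dists.mean()), float(0.5 * (dists.max() - dists.min()))


def region_nbi_count(
    springs: SpringSystem, chain: ChainModel, region: set[int] | list[tuple[int, int]]
) -> int:
    """Number of NBIs with exactly one atom inside the residue region
    (boundary-crossing interactions)."""
    if not isinstance(region, set):
        residues: set[int] = set()
        for lo, hi in region:
            residues.update(range(lo, hi + 1))
        region = residues
    if not region:
        raise ValueError("empty region")
    inside = np.array([a.residue_index in region for a in chain.atoms])
    count = 0
    for t in springs.nbi:
        if inside[t.atom_i] != inside[t.atom_j]:
            count += 1
    return count


def residue_tally(chain: ChainModel, residue_name: str) -> int:
    """Count of resolved residues with the given 3-letter code."""
    return sum(1 for _, name, _ in chain.residues if name == residue_name)


def region_report(
    analysis: ChainAnalysis,
    region_map: RegionMap,
    scheme: str,
    temperature: float = 180.0,
) -> dict:
    """Tally table for one chain: per-region NBI boundary counts and proline
    counts, with the intervals used."""
    chain = analysis.chain
    rows = {}
    for region in region_map.data[scheme]:
        residues = region_map.residues(scheme, region)
        resolved = residues & {r for r, _, _ in chain.residues}
        if not resolved:
            continue
        rows[region] = {
            "intervals": region_map.intervals(scheme, region),
            "n_residues_resolved": len(resolved),
            "boundary_nbi": region_nbi_count(analysis.springs, chain, resolved),
        }
    return {
        "chain": chain.chain_id,
        "scheme": scheme,
        "temperature": temperature,
        "prolines": residue_tally(chain, "PRO"),
        "regions": rows,
    }
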