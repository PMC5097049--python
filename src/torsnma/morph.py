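"""Mode-space morphing between conformers and assembly clash scanning.

Deformation is performed in torsion space with an exact internal-coordinate
rebuild: modal amplitudes add to the soft dihedral values, coordinates are
rebuilt holding every bond length and bond angle at the reference values, and
the result is rigid-superposed back onto the input.  A linear Cartesian
extrapolation (x + sum_k a_k field_k) is available behind a flag for
diagnostics only.

Amplitudes are modal coordinates in the generalized-mass-normalized basis;
the harmonic energy cost of amplitude a_k is E_k = 1/2 omega_k^2 a_k^2,
reported in units of k_B T_ref.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.optimize
from scipy.spatial import cKDTree

from .constants import KB_KCAL_MOL_K
from .geometry import kabsch
from .nma_engine import ChainAnalysis, ModeSet
from .structure_io import ChainModel
from .synthetic_data import perturb_along_torsions
from .topology import Topology

T_REF = 180.0  # K; thermal reference for amplitude/energy bookkeeping
MAIN_CHAIN_FIT_ATOMS = ("N", "CA", "C", "O")


def thermal_amplitude(modes: ModeSet, k: int, temperature: float = T_REF) -> float:
    """Peak amplitude of mode k (1-based) carrying k_B T of energy:
    a = sqrt(2 k_B T) / omega."""
    lam = modes.eigenvalues[k - 1]
    return float(np.sqrt(2.0 * KB_KCAL_MOL_K * temperature / lam))


def apply_mode_displacement(
    chain: ChainModel,
    topology: Topology,
    modes: ModeSet,
    amplitudes: np.ndarray,
    linear: bool = False,
) -> ChainModel:
    """Displace a chain along modes by the given amplitudes (exact torsional
    rebuild; ``linear=True`` switches to Cartesian extrapolation)."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    if not np.all(np.isfinite(amplitudes)):
        raise ValueError("amplitudes must be finite")
    if amplitudes.ndim != 1 or len(amplitudes) > modes.n_modes:
        raise ValueError("need one amplitude per used mode")
    if linear:
        disp = np.tensordot(amplitudes, modes.cartesian_fields[: len(amplitudes)], axes=1)
        return chain.with_coords(chain.coords + disp)
    deltas = modes.torsional_vectors[:, : len(amplitudes)] @ amplitudes
    deformed = perturb_along_torsions(chain, topology, deltas)
    R, t, _ = kabsch(deformed.coords, chain.coords)
    return deformed.with_coords(deformed.coords @ R.T + t)


@dataclass
class MorphResult:
    amplitudes: np.ndarray
    energy_kt: np.ndarray  # per-mode harmonic cost in k_B T_REF units
    relative_contributions: np.ndarray  # linear-norm definition, sums to 1
    relative_contributions_sq: np.ndarray  # squared-norm alternative
    rmsd_before: float
    rmsd_after: float
    deformed: ChainModel


def _pair_selection(
    source: ChainModel, target: ChainModel, atom_names: tuple[str, ...]
) -> tuple[list[int], list[int]]:
    names = set(atom_names)
    tgt = {
        (a.residue_index, a.name): i
        for i, a in enumerate(target.atoms)
        if a.name in names
    }
    si, ti = [], []
    for i, a in enumerate(source.atoms):
        if a.name in names and (a.residue_index, a.name) in tgt:
            si.append(i)
            ti.append(tgt[(a.residue_index, a.name)])
    return si, ti


def fit_modes_to_target(
    source: ChainModel,
    target: ChainModel,
    analysis: ChainAnalysis,
    k: int = 3,
    selection: tuple[str, ...] = MAIN_CHAIN_FIT_ATOMS,
    temperature: float = T_REF,
    sequential: bool = False,
) -> MorphResult:
    """Fit amplitudes of the k slowest modes of ``source`` that minimize the
    post-superposition RMSD to ``target`` over the selected atoms.

    Deterministic: a fixed multi-start lattice (each amplitude at
    0, ±0.5, ±1, ±2 thermal amplitudes) seeds a Nelder-Mead refinement; the
    k-mode search is additionally seeded with the (k-1)-mode optimum, so the
    fitted RMSD is non-increasing in k.  ``sequential=True`` instead optimizes
    one mode at a time (mode 1, then 2, ...) holding earlier amplitudes fixed,
    the natural bookkeeping for per-mode energy reports.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if sequential:
        return _fit_sequential(source, target, analysis, k, selection, temperature)
    modes = analysis.modes
    topo = analysis.topology
    si, ti = _pair_selection(source, target, selection)
    if len(si) < 3:
        raise ValueError("fewer than 3 paired atoms in the fit selection")
    tgt_xyz = target.coords[ti]

    def objective(amps: np.ndarray) -> float:
        deformed = apply_mode_displacement(source, topo, modes, amps)
        _, _, rmsd = kabsch(deformed.coords[si], tgt_xyz)
        if not np.isfinite(rmsd):
            raise ValueError("non-finite morph objective")
        return rmsd

    rmsd_before = objective(np.zeros(k))
    a_th = np.array([thermal_amplitude(modes, m + 1, temperature) for m in range(k)])

    starts: list[np.ndarray] = []
    if k > 1:
        prev = fit_modes_to_target(source, target, analysis, k - 1, selection, temperature)
        starts.append(np.concatenate([prev.amplitudes, [0.0]]))
    lattice = [(-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)] * k
    grid = [np.array(c) * a_th for c in itertools.product(*lattice)]
    grid_scores = [(objective(g), tuple(g)) for g in grid]
    grid_scores.sort(key=lambda t: t[0])
    starts.extend(np.array(g) for _, g in grid_scores[:3])

    best_amps, best_rmsd = np.zeros(k), rmsd_before
    for s in starts:
        res = scipy.optimize.minimize(
            objective, s, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400 * k},
        )
        if res.fun < best_rmsd:
            best_rmsd, best_amps = float(res.fun), np.asarray(res.x)

    field_norms = np.array(
        [np.linalg.norm(modes.cartesian_fields[m]) for m in range(k)]
    )
    weights = np.abs(best_amps) * field_norms
    total = weights.sum()
    contrib = weights / total if total > 0 else np.full(k, 1.0 / k)
    weights_sq = (best_amps * field_norms) ** 2
    total_sq = weights_sq.sum()
    contrib_sq = weights_sq / total_sq if total_sq > 0 else np.full(k, 1.0 / k)
    energy = 0.5 * modes.eigenvalues[:k] * best_amps**2 / (KB_KCAL_MOL_K * temperature)
    return MorphResult(
        amplitudes=best_amps,
        energy_kt=energy,
        relative_contributions=contrib,
        relative_contributions_sq=contrib_sq,
        rmsd_before=rmsd_before,
        rmsd_after=best_rmsd,
        deformed=apply_mode_displacement(source, topo, modes, best_amps),
    )


def _fit_sequential(source, target, analysis, k, selection, temperature) -> MorphResult:
    """One-mode-at-a-time greedy fit (earlier amplitudes frozen)."""
    modes = analysis.modes
    topo = analysis.topology
    si, ti = _pair_selection(source, target, selection)
    tgt_xyz = target.coords[ti]

    def objective(amps: np.ndarray) -> float:
        deformed = apply_mode_displacement(source, topo, modes, amps)
        _, _, rmsd = kabsch(deformed.coords[si], tgt_xyz)
        return rmsd

    amps = np.zeros(k)
    rmsd_before = objective(amps)
    for m in range(k):
        a_th = thermal_amplitude(modes, m + 1, temperature)

        def one(a: float) -> float:
            trial = amps.copy()
            trial[m] = a
            return objective(trial)

        starts = [c * a_th for c in (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)]
        best = min(starts, key=one)
        res = scipy.optimize.minimize_scalar(
            one, bounds=(best - a_th, best + a_th), method="bounded",
            options={"xatol": 1e-5},
        )
        amps[m] = float(res.x) if res.fun <= one(best) else best
    rmsd_after = objective(amps)
    field_norms = np.array([np.linalg.norm(modes.cartesian_fields[m]) for m in range(k)])
    weights = np.abs(amps) * field_norms
    total = weights.sum()
    contrib = weights / total if total > 0 else np.full(k, 1.0 / k)
    weights_sq = (amps * field_norms) ** 2
    contrib_sq = weights_sq / weights_sq.sum() if weights_sq.sum() > 0 else np.full(k, 1.0 / k)
    energy = 0.5 * modes.eigenvalues[:k] * amps**2 / (KB_KCAL_MOL_K * temperature)
    return MorphResult(
        amplitudes=amps,
        energy_kt=energy,
        relative_contributions=contrib,
        relative_contributions_sq=contrib_sq,
        rmsd_before=rmsd_before,
        rmsd_after=rmsd_after,
        deformed=apply_mode_displacement(source, topo, modes, amps),
    )


def clash_scan(
    analyses: list[ChainAnalysis],
    n_modes: int = 3,
    temperature: float = T_REF,
    threshold: float = 2.4,
) -> dict:
    """Scan an assembly for inter-chain heavy-atom clashes under simultaneous
    activation of each chain's isolated-monomer modes.

    Every chain is displaced along its own slowest ``n_modes`` modes at ±1
    thermal amplitude; the phase grid enumerates all sign combinations
    (applied congruently across chains).  Returns the baseline clash count of
    the deposited assembly and the per-phase counts and minimum inter-chain
    distances.
    """
    if not analyses:
        raise ValueError("empty assembly")

    def count(coord_sets: list[np.ndarray]) -> tuple[int, float]:
        total = 0
        dmin = np.inf
        trees = [cKDTree(c) for c in coord_sets]
        for a in range(len(coord_sets)):
            for b in range(a + 1, len(coord_sets)):
                total += int(trees[a].count_neighbors(trees[b], threshold))
                d, _ = trees[a].query(coord_sets[b], k=1)
                dmin = min(dmin, float(np.min(d)))
        return total, dmin

    baseline_coords = [an.chain.coords for an in analyses]
    baseline_clashes, baseline_min = count(baseline_coords)

    phases = list(itertools.product((-1.0, 1.0), repeat=n_modes))
    results = []
    for signs in phases:
        coord_sets = []
        for an in analyses:
            amps = np.array(
                [s * thermal_amplitude(an.modes, m + 1, temperature)
                 for m, s in enumerate(signs)]
            )
            deformed = apply_mode_displacement(an.chain, an.topology, an.modes, amps)
            # keep the assembly frame: superpose the deformed chain back is
            # already done inside apply_mode_displacement
            coord_sets.append(deformed.coords)
        c, dmin = count(coord_sets)
        results.append({"phases": signs, "clashes": c, "min_distance": dmin})
    return {
        "threshold": threshold,
        "baseline_clashes": baseline_clashes,
        "baseline_min_distance": baseline_min,
        "scan": results,
        "max_clashes": max(r["clashes"] for r in results),
    }
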