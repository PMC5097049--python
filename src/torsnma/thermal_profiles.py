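"""Thermal motility profiles: RMSF and Debye-Waller (B) factors from modes.

Classical equipartition per mode: at temperature T the mean-square modal
amplitude is <q_k^2> = k_B T / omega_k^2 in generalized-mass-normalized
coordinates, so the per-atom mean-square displacement of a mode subset is the
quadrature sum over the subset's Cartesian fields.  B-factors follow as
B = (8 pi^2 / 3) <dr^2> and are compared *unscaled* against deposited values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import B_FROM_MSD, KB_KCAL_MOL_K
from .nma_engine import ModeSet
from .structure_io import ChainModel


@dataclass
class MotilityProfile:
    """Per-atom thermal fluctuation amplitudes for a mode subset."""

    rmsf: np.ndarray  # per-atom, Å
    mode_subset: tuple[int, ...]  # 1-based mode indices
    temperature: float  # K
    ca_indices: tuple[int, ...]
    residue_indices: tuple[int, ...]

    @property
    def b(self) -> np.ndarray:
        """Per-atom B-factor, Å^2: B = (8 pi^2 / 3) RMSF^2."""
        return B_FROM_MSD * self.rmsf**2

    @property
    def rmsf_ca(self) -> np.ndarray:
        return self.rmsf[list(self.ca_indices)]

    @property
    def b_ca(self) -> np.ndarray:
        return self.b[list(self.ca_indices)]


def mode_rmsf(
    modes: ModeSet,
    subset: list[int] | tuple[int, ...] | range,
    temperature: float,
    chain: ChainModel,
) -> MotilityProfile:
    """Per-atom RMSF (Å) from thermally activated modes.

    ``subset`` holds 1-based mode indices (mode 1 = slowest).  RMSF_a =
    sqrt(sum_k (k_B T / omega_k^2) |c_{a,k}|^2).
    """
    subset = tuple(sorted(int(k) for k in subset))  # canonical accumulation order
    if not subset:
        raise ValueError("mode subset must be non-empty")
    if min(subset) < 1 or max(subset) > modes.n_modes:
        raise ValueError(f"mode indices out of range 1..{modes.n_modes}")
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    kt = KB_KCAL_MOL_K * temperature
    msd = np.zeros(modes.cartesian_fields.shape[1])
    for k in subset:
        field = modes.cartesian_fields[k - 1]
        msd += (kt / modes.eigenvalues[k - 1]) * np.sum(field**2, axis=1)
    cas = tuple(chain.ca_indices())
    res_ids = tuple(chain.atoms[i].residue_index for i in cas)
    return MotilityProfile(
        rmsf=np.sqrt(msd),
        mode_subset=subset,
        temperature=temperature,
        ca_indices=cas,
        residue_indices=res_ids,
    )


def rmsf_contribution(
    modes: ModeSet, subset: list[int], temperature: float, chain: ChainModel,
) -> dict[str, float]:
    """Fraction of the all-mode per-Calpha RMSF carried by a mode subset.

    Primary definition: ratio of summed per-Calpha RMSF (subset over all
    modes).  The quadrature alternative (ratio of summed mean-square
    displacements) is returned alongside.
    """
    sub = mode_rmsf(modes, subset, temperature, chain)
    full = mode_rmsf(modes, range(1, modes.n_modes + 1), temperature, chain)
    linear = float(np.sum(sub.rmsf_ca) / np.sum(full.rmsf_ca))
    quadrature = float(np.sum(sub.rmsf_ca**2) / np.sum(full.rmsf_ca**2))
    return {"linear": linear, "quadrature": quadrature}


def bfactor_cross_correlation(computed: np.ndarray, experimental: np.ndarray) -> float:
    """Pearson correlation between computed and experimental per-Calpha
    B-factors over shared positions (NaNs excluded pairwise)."""
    x = np.asarray(computed, dtype=float)
    y = np.asarray(experimental, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must be aligned to the same residues")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError("need at least 3 shared residues")
    x, y = x[mask], y[mask]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a B-factor profile")
    return float(np.corrcoef(x, y)[0, 1])


def region_average(
    values: np.ndarray,
    residue_indices: np.ndarray | tuple[int, ...],
    region: list[tuple[int, int]] | list[list[int]],
) -> float:
    """Arithmetic mean of per-Calpha values over a residue-interval set."""
    res = np.asarray(residue_indices)
    vals = np.asarray(values, dtype=float)
    mask = np.zeros(len(res), dtype=bool)
    for lo, hi in region:
        mask |= (res >= lo) & (res <= hi)
    if not mask.any():
        raise ValueError(f"region {region} contains no resolved residues")
    return float(np.mean(vals[mask]))
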