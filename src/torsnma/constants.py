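"""Physical constants and the internal unit system.

Internal units throughout the package: energy kcal/mol, length Å, mass amu,
angle rad.  Every conversion between these units and SI/spectroscopic units
lives here; no other module hard-codes a conversion factor.
"""

import math

# CODATA-ish values, more precision than the method needs.
KCAL_PER_MOL_IN_J = 4184.0 / 6.02214076e23  # J per molecule
AMU_IN_KG = 1.66053906660e-27
ANGSTROM_IN_M = 1e-10
C_CM_PER_S = 2.99792458e10

# Boltzmann constant in internal energy units.
KB_KCAL_MOL_K = 0.001987204259

#: sqrt(1 kcal/mol / (amu Å^2)) expressed as a wavenumber in cm^-1.
#: An angular frequency omega = sqrt(lambda) with lambda in internal units
#: corresponds to the wavenumber lambda**0.5 * WAVENUMBER_PER_SQRT_INTERNAL.
WAVENUMBER_PER_SQRT_INTERNAL = (
    math.sqrt(KCAL_PER_MOL_IN_J / (AMU_IN_KG * ANGSTROM_IN_M**2))
    / (2.0 * math.pi * C_CM_PER_S)
)

# Average atomic masses (amu) for protein heavy atoms.
ATOMIC_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

# Main-chain heavy atom names; everything else is side chain.
MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: B-factor from mean-square displacement: B = (8 pi^2 / 3) <dr^2>.
B_FROM_MSD = 8.0 * math.pi**2 / 3.0


def eigenvalue_to_wavenumber(lam: float) -> float:
    """Convert a generalized eigenvalue (internal units, omega^2) to cm^-1."""
    if lam < 0:
        raise ValueError(f"negative eigenvalue {lam!r} has no real frequency")
    return math.sqrt(lam) * WAVENUMBER_PER_SQRT_INTERNAL


def element_of(atom_name: str) -> str:
    """Element symbol for a standard protein heavy-atom name (e.g. OG1 -> O)."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")
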