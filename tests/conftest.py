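"""Shared fixtures: synthetic structures and their full analyses.

The crystal-structure regression tier (bovine F1-ATPase, PDB 2JDI) activates
only when a local copy of the coordinate file is present (tests call
``require_2jdi``); everything else is generated programmatically.
"""

from __future__ import annotations

from pathlib import Path

import pytest

import torsnma as t

REPO_ROOT = Path(__file__).resolve().parent.parent
_2JDI_CANDIDATES = [
    REPO_ROOT / "2JDI.pdb",
    REPO_ROOT / "2jdi.pdb",
    REPO_ROOT / "data" / "2JDI.pdb",
    REPO_ROOT / "data" / "2jdi.pdb",
]


def require_2jdi() -> Path:
    for p in _2JDI_CANDIDATES:
        if p.exists():
            return p
    pytest.skip(
        "requires a local copy of PDB 2JDI (place 2JDI.pdb in the repository "
        "root or data/); this regression tier cannot run offline"
    )


@pytest.fixture(scope="session")
def dumbbell_chain() -> t.ChainModel:
    return t.build_dumbbell(helix_len=10, linker=3, seed=0)


@pytest.fixture(scope="session")
def dumbbell_analysis(dumbbell_chain) -> t.ChainAnalysis:
    return t.analyze_chain(dumbbell_chain)


@pytest.fixture(scope="session")
def tripeptide_chain() -> t.ChainModel:
    # Ala-Ser-Lys: one chi on Ser, four on Lys, compact backbone
    spec = t.PeptideSpec(
        "ASK", ((-57.0, -47.0), (-57.0, -47.0), (-57.0, -47.0))
    )
    return t.build_peptide(spec)


@pytest.fixture(scope="session")
def tripeptide_analysis(tripeptide_chain) -> t.ChainAnalysis:
    return t.analyze_chain(tripeptide_chain)


@pytest.fixture(scope="session")
def all_residue_chain() -> t.ChainModel:
    """One chain containing every standard residue type, helix-like."""
    seq = "ACDEFGHIKLMNPQRSTVWY"
    spec = t.PeptideSpec(seq, tuple([(-64.0, -42.0)] * len(seq)))
    return t.build_peptide(spec)
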