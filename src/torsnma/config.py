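"""Loading of the versioned parameter/data tables shipped with the package.

Three tables exist: the residue template table (connectivity, chi definitions,
internal-coordinate build recipes), the Hookean force-field parameters and the
subunit region map.  Users may pass alternative files anywhere a table is
consumed; all published-number comparisons should state which files were used.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml


def _load_yaml(name_or_path: str | Path, packaged: bool) -> dict[str, Any]:
    if packaged:
        text = resources.files("torsnma.data").joinpath(str(name_or_path)).read_text()
    else:
        text = Path(name_or_path).read_text()
    return yaml.safe_load(text)


@functools.lru_cache(maxsize=8)
def load_residue_templates(path: str | None = None) -> dict[str, Any]:
    """Residue template table; packaged default when ``path`` is None."""
    if path is None:
        return _load_yaml("residues.yaml", packaged=True)
    return _load_yaml(path, packaged=False)


@dataclass(frozen=True)
class GaussianWell:
    phi: float
    psi: float
    depth: float
    width: float  # degrees


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field parameter set in internal units (angles kept in degrees)."""

    lj_sigma: dict[str, float]
    lj_epsilon: dict[str, float]
    lj_combine: str = "arithmetic"
    nbi_profile: str = "constant"
    nbi_k: float = 1.0
    global_scale: float = 1.0
    k_chi: float = 6.0
    curvature_floor: float = 0.5
    phipsi_wells: tuple[GaussianWell, ...] = field(default_factory=tuple)
    source: str = "packaged forcefield.yaml v1"

    def sigma_pair(self, elem_i: str, elem_j: str) -> float:
        try:
            si, sj = self.lj_sigma[elem_i], self.lj_sigma[elem_j]
        except KeyError as exc:
            raise KeyError(f"no LJ class for element {exc.args[0]!r}") from exc
        if self.lj_combine == "arithmetic":
            return 0.5 * (si + sj)
        if self.lj_combine == "geometric":
            return (si * sj) ** 0.5
        raise ValueError(f"unknown LJ combining rule {self.lj_combine!r}")

    def epsilon_pair(self, elem_i: str, elem_j: str) -> float:
        return (self.lj_epsilon[elem_i] * self.lj_epsilon[elem_j]) ** 0.5


def load_forcefield_params(path: str | None = None) -> ForceFieldParams:
    raw = _load_yaml(path or "forcefield.yaml", packaged=path is None)
    wells = tuple(GaussianWell(**w) for w in raw["torsion"].get("phipsi_wells", []))
    return ForceFieldParams(
        lj_sigma=dict(raw["lj"]["sigma"]),
        lj_epsilon=dict(raw["lj"]["epsilon"]),
        lj_combine=raw["lj"].get("combine", "arithmetic"),
        nbi_profile=raw["nbi"].get("profile", "constant"),
        nbi_k=float(raw["nbi"].get("k", 1.0)),
        global_scale=float(raw["nbi"].get("global_scale", 1.0)),
        k_chi=float(raw["torsion"].get("k_chi", 6.0)),
        curvature_floor=float(raw["torsion"].get("curvature_floor", 0.5)),
        phipsi_wells=wells,
        source=str(path) if path else "packaged forcefield.yaml v1",
    )


def load_region_map(path: str | None = None) -> dict[str, dict[str, list[list[int]]]]:
    raw = _load_yaml(path or "regions.yaml", packaged=path is None)
    return {k: v for k, v in raw.items() if k != "version"}
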