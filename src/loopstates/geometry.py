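"""Structural measurement primitives.

Superposition/RMSD (Kabsch), centers of mass, minimum inter-residue
distances, Shrake-Rupley solvent-accessible surface area, radius of
gyration and the Matthews coefficient.  All distances are Å, areas Å²,
masses Da.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Atom, Conformer, Residue

logger = logging.getLogger(__name__)

__all__ = [
    "SuperpositionResult",
    "CellParams",
    "GeometryError",
    "kabsch_superpose_rmsd",
    "center_of_mass",
    "min_residue_distance",
    "shrake_rupley_asa",
    "radius_of_gyration",
    "matthews_solvent",
    "ATOMIC_MASSES",
    "VDW_RADII",
]


class GeometryError(ValueError):
    """Degenerate geometric input (too few points, empty scope, ...)."""


# Average isotopic masses (Da) for elements occurring in protein structures
# and common cofactors.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "CU": 63.546, "FE": 55.845, "ZN": 65.38,
    "MG": 24.305, "MN": 54.938, "NA": 22.990, "CL": 35.45, "CA": 40.078,
    "K": 39.098, "BR": 79.904, "I": 126.904,
}

# Bondi-type van der Waals radii (Å) used by the Shrake-Rupley surface.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "CU": 1.40, "FE": 1.40, "ZN": 1.39, "MG": 1.73,
    "MN": 1.40, "NA": 2.27, "CL": 1.75, "CA": 2.31, "K": 2.75,
    "BR": 1.85, "I": 1.98,
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def _element_key(element: str) -> str:
    return element.strip().upper()


def atomic_mass(element: str) -> float:
    key = _element_key(element)
    if key not in ATOMIC_MASSES:
        raise GeometryError(f"no atomic mass for element {element!r}")
    return ATOMIC_MASSES[key]


@dataclass
class SuperpositionResult:
    """Optimal rigid-body superposition: rotation, translation and the RMSD it attains."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class CellParams:
    """Crystal cell volume (Å³), molecule count per cell and molecular mass (Da)."""

    cell_volume: float
    molecules_per_cell: int
    molecular_mass: float

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.molecules_per_cell <= 0 or self.molecular_mass <= 0:
            raise ValueError("all cell parameters must be positive")


def kabsch_superpose_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal (weighted) rigid superposition of ``coords_b`` onto ``coords_a``.

    Returns the proper rotation R and translation t minimising the
    (weighted) RMSD of ``coords_b @ R.T + t`` to ``coords_a``, via the
    SVD of the cross-covariance with reflection correction.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise GeometryError(f"coordinate sets must share an (N, 3) shape; got {a.shape}, {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 points to superpose, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise GeometryError("weights must be a non-negative N-vector with positive sum")
    w = w / w.sum()

    ca = (w[:, None] * a).sum(axis=0)
    cb = (w[:, None] * b).sum(axis=0)
    a0, b0 = a - ca, b - cb
    h = (w[:, None] * b0).T @ a0
    u, sing, vt = np.linalg.svd(h)
    if sing[1] < 1e-12:  # rank < 2: collinear or coincident points
        raise GeometryError("degenerate (collinear) coordinates: superposition not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = b0 @ rot.T - a0
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))
    trans = ca - cb @ rot.T
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def center_of_mass(atoms: list[Atom], mass_weighted: bool = True) -> np.ndarray:
    """Mass-weighted mean position (standard atomic masses), or plain centroid."""
    if not atoms:
        raise GeometryError("center_of_mass of an empty atom list")
    pos = np.array([a.position for a in atoms])
    if not mass_weighted:
        return pos.mean(axis=0)
    masses = np.array([atomic_mass(a.element) for a in atoms])
    return (masses[:, None] * pos).sum(axis=0) / masses.sum()


def _scope_atoms(res: Residue, atom_scope: str) -> list[Atom]:
    if atom_scope == "all":
        return res.atoms
    if atom_scope == "heavy":
        return [a for a in res.atoms if _element_key(a.element) != "H"]
    if atom_scope == "sidechain-heavy":
        return [
            a for a in res.atoms
            if _element_key(a.element) != "H" and a.name not in _BACKBONE_NAMES
        ]
    raise ValueError(f"unknown atom scope {atom_scope!r}")


def min_residue_distance(res_a: Residue, res_b: Residue, atom_scope: str = "heavy") -> float:
    """Minimum pairwise atom distance between two residues over the given scope."""
    atoms_a = _scope_atoms(res_a, atom_scope)
    atoms_b = _scope_atoms(res_b, atom_scope)
    if not atoms_a or not atoms_b:
        raise GeometryError(
            f"scope {atom_scope!r} empty on residue "
            f"{res_a.key if not atoms_a else res_b.key}"
        )
    pa = np.array([a.position for a in atoms_a])
    pb = np.array([a.position for a in atoms_b])
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.min()))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _load_max_asa() -> dict[str, float]:
    table = {}
    text = resources.files("loopstates.data").joinpath("max_asa.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, value = line.split("\t")
        table[name] = float(value)
    return table


_MAX_ASA: dict[str, float] | None = None


def shrake_rupley_asa(
    model: Conformer,
    probe_radius: float = 1.4,
    n_points: int = 960,
    report: str = "absolute",
    radii: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-residue solvent-accessible surface area by the Shrake-Rupley method.

    Each atom is inflated by ``probe_radius`` and sampled with ``n_points``
    quasi-uniform sphere points; a point is accessible when outside every
    neighbouring inflated sphere.  Returns a table with columns
    ``(chain, number, name, asa_A2, rel_pct)``; the relative percentage
    divides by a fixed per-residue-type reference maximum and is NaN for
    residue types absent from that table (ligands, single-bead toys).

    ``report`` selects which column downstream summaries emphasise but both
    are always computed.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a stable estimate")
    if report not in ("absolute", "relative"):
        raise ValueError(f"unknown report mode {report!r}")
    radii = radii or VDW_RADII

    atoms = list(model.atoms())
    pos = np.array([a.position for a in atoms])
    try:
        rad = np.array([radii[_element_key(a.element)] for a in atoms])
    except KeyError as exc:
        raise GeometryError(f"no van der Waals radius for element {exc.args[0]!r}") from exc
    inflated = rad + probe_radius

    unit = _sphere_points(n_points)
    tree = cKDTree(pos)
    max_r = inflated.max()
    per_atom = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = pos[i] + inflated[i] * unit
        neighbours = [j for j in tree.query_ball_point(pos[i], inflated[i] + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = ((pts - pos[j]) ** 2).sum(axis=1)
            accessible &= d2 > inflated[j] ** 2
            if not accessible.any():
                break
        per_atom[i] = 4.0 * np.pi * inflated[i] ** 2 * accessible.sum() / n_points

    global _MAX_ASA
    if _MAX_ASA is None:
        _MAX_ASA = _load_max_asa()
    rows = []
    k = 0
    for res in model.residues:
        n_at = len(res.atoms)
        asa = per_atom[k : k + n_at].sum()
        k += n_at
        ref = _MAX_ASA.get(res.name)
        rows.append({
            "chain": res.chain,
            "number": res.number,
            "name": res.name,
            "asa_A2": asa,
            "rel_pct": 100.0 * asa / ref if ref else np.nan,
        })
    return pd.DataFrame(rows)


def radius_of_gyration(model: Conformer, mass_weighted: bool = True) -> float:
    """Root-mean-square (weighted) distance of atoms from their center of mass."""
    atoms = list(model.atoms())
    if not atoms:
        raise GeometryError("radius_of_gyration of an empty model")
    pos = np.array([a.position for a in atoms])
    w = (
        np.array([atomic_mass(a.element) for a in atoms])
        if mass_weighted
        else np.ones(len(atoms))
    )
    com = (w[:, None] * pos).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((pos - com) ** 2).sum(axis=1)).sum() / w.sum()))


def matthews_solvent(cp: CellParams) -> tuple[float, float]:
    """Matthews coefficient V_M (Å³/Da) and the solvent content (%) it implies.

    V_M = V_cell / (Z * M); solvent % = (1 - 1.23 / V_M) * 100, using the
    standard protein partial specific volume.  A V_M at or below 1.23
    (physically impossible packing) is returned with a logged warning.
    """
    vm = cp.cell_volume / (cp.molecules_per_cell * cp.molecular_mass)
    solvent = (1.0 - 1.23 / vm) * 100.0
    if vm <= 1.23:
        logger.warning("V_M %.3f <= 1.23: negative solvent content %.1f%%", vm, solvent)
    return float(vm), float(solvent)
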