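"""Docking-pose geometry statistics.

Consumes pose sets (ligand coordinates + score per pose, decoupled from
any docking engine) and produces pose-to-site distance vectors, binned
histograms and per-bin score summaries — the standard way of asking
whether a substrate can reach electron-transfer distance of a redox
centre across an ensemble of docking solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import Atom, read_pdb_models

__all__ = [
    "Pose",
    "PoseSet",
    "DistanceHistogram",
    "pose_site_distances",
    "distance_histogram",
    "read_pose_set",
    "write_pose_set",
]


@dataclass
class Pose:
    pose_id: str
    ligand_atoms: list[Atom]
    score: float  # kcal/mol

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise ValueError(f"pose {self.pose_id}: no ligand atoms")

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.ligand_atoms])


@dataclass
class PoseSet:
    """Docking poses plus named reference-site positions on the receptor."""

    poses: list[Pose]
    receptor_sites: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.pose_id for p in self.poses]
        if len(set(ids)) != len(ids):
            raise ValueError("pose ids must be unique")
        self.receptor_sites = {
            k: np.asarray(v, dtype=float) for k, v in self.receptor_sites.items()
        }

    def __len__(self) -> int:
        return len(self.poses)

    def scores(self) -> np.ndarray:
        return np.array([p.score for p in self.poses])


@dataclass
class DistanceHistogram:
    """Binned pose-to-site distances with per-bin docking-score summaries."""

    bin_edges: np.ndarray
    counts: np.ndarray
    overflow: int
    score_mean: np.ndarray
    score_min: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "count": self.counts,
            "score_mean": self.score_mean,
            "score_min": self.score_min,
        })


def pose_site_distances(
    poses: PoseSet,
    site: str | np.ndarray,
    metric: str = "min-atom",
) -> np.ndarray:
    """Per-pose distance (Å) to a reference site.

    ``metric`` is ``"min-atom"`` (closest ligand heavy atom) or
    ``"ligand-centroid"`` (unweighted ligand centroid).
    """
    if isinstance(site, str):
        if site not in poses.receptor_sites:
            raise KeyError(
                f"unknown reference site {site!r}; available: {sorted(poses.receptor_sites)}"
            )
        site_pos = poses.receptor_sites[site]
    else:
        site_pos = np.asarray(site, dtype=float)
    out = np.empty(len(poses))
    for i, pose in enumerate(poses.poses):
        xyz = pose.coords()
        if metric == "min-atom":
            heavy = np.array(
                [a.position for a in pose.ligand_atoms if a.element.strip().upper() != "H"]
            )
            xyz = heavy if heavy.size else xyz
            out[i] = np.sqrt(((xyz - site_pos) ** 2).sum(axis=1)).min()
        elif metric == "ligand-centroid":
            out[i] = np.sqrt(((xyz.mean(axis=0) - site_pos) ** 2).sum())
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return out


def distance_histogram(
    distances: np.ndarray,
    bin_width: float = 0.5,
    bin_range: tuple[float, float] = (2.0, 20.0),
    scores: np.ndarray | None = None,
) -> DistanceHistogram:
    """Histogram pose distances on half-open bins [lo + k w, lo + (k+1) w).

    Out-of-range poses are counted in ``overflow`` rather than dropped,
    so counts + overflow always equals the number of input poses.  When
    ``scores`` is given, each bin also carries the mean and best
    (minimum) docking score of its poses.
    """
    lo, hi = bin_range
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if hi <= lo:
        raise ValueError("bin range upper bound must exceed lower bound")
    d = np.asarray(distances, dtype=float)
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    score_sum = np.zeros(n_bins)
    score_min = np.full(n_bins, np.nan)
    overflow = 0
    s = np.asarray(scores, dtype=float) if scores is not None else None
    for i, x in enumerate(d):
        k = int(np.floor((x - lo) / bin_width))
        if 0 <= k < n_bins:
            counts[k] += 1
            if s is not None:
                score_sum[k] += s[i]
                score_min[k] = s[i] if np.isnan(score_min[k]) else min(score_min[k], s[i])
        else:
            overflow += 1
    with np.errstate(invalid="ignore"):
        score_mean = np.where(counts > 0, score_sum / np.maximum(counts, 1), np.nan)
    return DistanceHistogram(
        bin_edges=edges, counts=counts, overflow=overflow,
        score_mean=score_mean, score_min=score_min,
    )


def read_pose_set(
    pose_dir: str | Path,
    score_table: str | Path,
    receptor_sites: dict[str, np.ndarray] | None = None,
) -> PoseSet:
    """Load poses from a directory of ligand PDB files plus a score CSV.

    The CSV must have columns ``pose_id`` and ``score_kcal_mol``; each
    pose_id names a file ``<pose_id>.pdb`` in ``pose_dir``.
    """
    pose_dir = Path(pose_dir)
    table = pd.read_csv(score_table)
    for col in ("pose_id", "score_kcal_mol"):
        if col not in table.columns:
            raise ValueError(f"score table lacks required column {col!r}")
    poses = []
    for row in table.itertuples(index=False):
        path = pose_dir / f"{row.pose_id}.pdb"
        if not path.exists():
            raise FileNotFoundError(f"pose file missing: {path}")
        ens = read_pdb_models(path)
        atoms = [a for a in ens[0].atoms()]
        poses.append(Pose(pose_id=str(row.pose_id), ligand_atoms=atoms,
                          score=float(row.score_kcal_mol)))
    return PoseSet(poses=poses, receptor_sites=receptor_sites or {})


def write_pose_set(poses: PoseSet, pose_dir: str | Path, score_table: str | Path) -> None:
    """Write each pose as ``<pose_id>.pdb`` plus a pose_id/score CSV."""
    from .structure_io import ConformerEnsemble, Conformer, Residue, write_pdb_models

    pose_dir = Path(pose_dir)
    pose_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pose in poses.poses:
        res = Residue(chain="L", number=1, name="LIG", atoms=pose.ligand_atoms)
        ens = ConformerEnsemble(conformers=[Conformer(model_id=1, residues=[res])])
        write_pdb_models(ens, pose_dir / f"{pose.pose_id}.pdb")
        rows.append({"pose_id": pose.pose_id, "score_kcal_mol": pose.score})
    pd.DataFrame(rows).to_csv(score_table, index=False)
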