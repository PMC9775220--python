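"""Trajectory statistics and correlation-weighted residue networks.

Covers the analysis layer applied to molecular-dynamics output: RMSF,
Cα-covariance principal components, dynamic cross-correlation (DCC),
and the protein residue network (PRN) built from DCC, on which optimal
and suboptimal communication paths are found and compared between a
variant and a reference (the stronger the correlation between two
residues in contact, the shorter the edge joining them).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .geometry import center_of_mass, kabsch_superpose_rmsd
from .structure_io import Conformer, ConformerEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "DCCMatrix",
    "PCAResult",
    "PathSet",
    "rmsf",
    "dcc_matrix",
    "covariance_pca",
    "build_network",
    "shortest_paths",
    "path_delta_ranking",
]

ResidueKey = tuple[str, int, str]


@dataclass
class Trajectory:
    """Ordered frames sharing one residue topology, with a ns/frame tag."""

    frames: list[Conformer]
    frame_interval: float = 1.0  # ns per stored frame (metadata only)

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        ConformerEnsemble(conformers=list(self.frames))  # topology check

    def __len__(self) -> int:
        return len(self.frames)

    def residue_keys(self) -> list[ResidueKey]:
        return [r.key for r in self.frames[0].residues]

    def coords(self, atom_name: str | None = "CA") -> np.ndarray:
        """(T, R, 3) array of one representative atom per residue.

        ``atom_name`` picks that atom (falling back to the first atom of
        a residue that lacks it, e.g. single-bead toy residues); None
        always takes the first atom.
        """
        out = []
        for frame in self.frames:
            rows = []
            for res in frame.residues:
                atom = None
                if atom_name is not None:
                    atom = next((a for a in res.atoms if a.name == atom_name), None)
                rows.append((atom or res.atoms[0]).position)
            out.append(rows)
        return np.array(out)


@dataclass
class DCCMatrix:
    """Symmetric residue-residue displacement correlation matrix, C_ij in [-1, 1]."""

    values: np.ndarray
    residue_index: list[ResidueKey]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        r = len(self.residue_index)
        if v.shape != (r, r):
            raise ValueError("matrix shape must match the residue index")
        if np.abs(v - v.T).max() > 1e-9 or np.abs(np.diag(v) - 1.0).max() > 1e-9:
            raise ValueError("DCC matrix must be symmetric with unit diagonal")
        self.values = v

    def __sub__(self, other: "DCCMatrix") -> pd.DataFrame:
        """Elementwise difference as a labelled frame (variant-minus-reference maps)."""
        if self.residue_index != other.residue_index:
            raise ValueError("DCC matrices cover different residues")
        labels = [f"{c}{n}{i}" for c, n, i in self.residue_index]
        return pd.DataFrame(self.values - other.values, index=labels, columns=labels)


@dataclass
class PCAResult:
    """Eigenmodes of the aligned Cα positional covariance."""

    eigenvalues: np.ndarray  # descending, Å^2
    components: np.ndarray   # (3R, n_modes), orthonormal columns
    projections: np.ndarray  # (T, n_modes)

    def variance_fraction(self, mode: int) -> float:
        total = self.eigenvalues.sum()
        return float(self.eigenvalues[mode] / total) if total > 0 else 0.0


@dataclass
class PathSet:
    """Optimal plus suboptimal loopless paths between one residue pair."""

    source: ResidueKey
    target: ResidueKey
    paths: list[list[ResidueKey]] = field(default_factory=list)
    lengths: np.ndarray = field(default_factory=lambda: np.array([]))
    reachable: bool = True


# ---------------------------------------------------------------------------
# trajectory statistics
# ---------------------------------------------------------------------------

def _align_frames(x: np.ndarray, n_passes: int = 2) -> np.ndarray:
    """Kabsch-superpose every frame onto the running mean structure (two-pass)."""
    aligned = x.copy()
    ref = aligned.mean(axis=0)
    for _ in range(n_passes):
        for t in range(aligned.shape[0]):
            sup = kabsch_superpose_rmsd(ref, aligned[t])
            aligned[t] = sup.apply(aligned[t])
        ref = aligned.mean(axis=0)
    return aligned


def rmsf(traj: Trajectory, atom_name: str | None = "CA", align: bool = True) -> np.ndarray:
    """Per-residue root-mean-square fluctuation about the trajectory mean (Å).

    With ``align`` every frame is first rigid-body superposed onto the
    mean structure (iterated mean/align/re-mean), so rigid global motion
    contributes nothing.
    """
    x = traj.coords(atom_name)
    if align:
        x = _align_frames(x)
    mean = x.mean(axis=0)
    return np.sqrt(((x - mean) ** 2).sum(axis=2).mean(axis=0))


def dcc_matrix(traj: Trajectory, stride: int = 1, atom_name: str | None = "CA",
               align: bool = True) -> DCCMatrix:
    """Dynamic cross-correlation of residue displacement vectors.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) over aligned frames,
    dr = r - <r> (scalar dot-product correlation of 3-D displacements).
    Residues with zero displacement variance get zeroed rows/columns
    (diagonal stays 1) with a logged notice.
    """
    x = traj.coords(atom_name)[::stride]
    if x.shape[0] < 10:
        raise ValueError(f"need >= 10 frames after stride, have {x.shape[0]}")
    if align:
        x = _align_frames(x)
    delta = x - x.mean(axis=0)
    inner = np.einsum("tid,tjd->ij", delta, delta) / delta.shape[0]
    var = np.diag(inner).copy()
    dead = var <= 1e-12 * max(float(var.max()), 1e-300)
    if dead.any():
        logger.info("%d residues with zero displacement variance", int(dead.sum()))
        var[dead] = 1.0
    c = inner / np.sqrt(np.outer(var, var))
    c[dead, :] = 0.0
    c[:, dead] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(0.5 * (c + c.T), -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return DCCMatrix(values=c, residue_index=traj.residue_keys())


def covariance_pca(traj: Trajectory, stride: int = 1, atom_name: str | None = "CA",
                   align: bool = True) -> PCAResult:
    """Eigendecomposition of the 3R x 3R aligned Cα positional covariance.

    Rank deficiency (fewer frames than coordinates) is allowed; trailing
    eigenvalues are simply zero.
    """
    x = traj.coords(atom_name)[::stride]
    if align:
        x = _align_frames(x)
    t = x.shape[0]
    flat = x.reshape(t, -1)
    flat = flat - flat.mean(axis=0)
    cov = flat.T @ flat / (t - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return PCAResult(eigenvalues=evals, components=evecs, projections=flat @ evecs)


# ---------------------------------------------------------------------------
# residue network and communication paths
# ---------------------------------------------------------------------------

def build_network(
    mean_structure: Conformer,
    dcc: DCCMatrix,
    cutoff: float = 4.5,
    weight_scheme: str = "-ln",
) -> nx.Graph:
    """Correlation-weighted residue network.

    Nodes are residues (keyed by (chain, number, icode)) positioned at
    the mass-weighted residue centers of mass of ``mean_structure``; an
    edge joins residues whose centers lie within ``cutoff`` Å and whose
    |C_ij| > 0, carrying weight -ln|C_ij| (default) or 1 - |C_ij|, so a
    stronger correlation gives a shorter edge.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    keys = [r.key for r in mean_structure.residues]
    if keys != dcc.residue_index:
        raise ValueError("DCC residues do not match the mean structure")
    coms = np.array([center_of_mass(r.atoms) for r in mean_structure.residues])
    g = nx.Graph(contact_cutoff=cutoff, weight_scheme=weight_scheme)
    for key, com in zip(keys, coms):
        g.add_node(key, pos=com)
    n = len(keys)
    d2 = ((coms[:, None, :] - coms[None, :, :]) ** 2).sum(axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] > cutoff ** 2:
                continue
            c = abs(dcc.values[i, j])
            if c <= 0.0:
                continue
            if weight_scheme == "-ln":
                w = -np.log(min(c, 1.0))
            elif weight_scheme == "1-abs":
                w = 1.0 - min(c, 1.0)
            else:
                raise ValueError(f"unknown weight scheme {weight_scheme!r}")
            g.add_edge(keys[i], keys[j], weight=float(w), correlation=float(dcc.values[i, j]))
    return g


def shortest_paths(net: nx.Graph, source: ResidueKey, target: ResidueKey,
                   k: int = 15) -> PathSet:
    """Optimal plus up to k-1 suboptimal loopless paths (Yen's algorithm).

    Paths come out sorted by length, ties broken by lexicographic node
    order; an unreachable pair yields an empty PathSet flagged
    unreachable.
    """
    if not 1 <= k <= 15:
        raise ValueError("k must be between 1 and 15")
    for node in (source, target):
        if node not in net:
            raise KeyError(f"node {node} not in network")
    try:
        gen = nx.shortest_simple_paths(net, source, target, weight="weight")
        raw = list(itertools.islice(gen, k))
    except nx.NetworkXNoPath:
        return PathSet(source=source, target=target, reachable=False)

    def plen(path):
        return sum(net[u][v]["weight"] for u, v in zip(path, path[1:]))

    scored = sorted(((plen(p), p) for p in raw), key=lambda t: (round(t[0], 12), t[1]))
    return PathSet(
        source=source,
        target=target,
        paths=[p for _, p in scored],
        lengths=np.array([l for l, _ in scored]),
    )


def path_delta_ranking(
    net_a: nx.Graph,
    net_b: nx.Graph,
    pairs: list[tuple[ResidueKey, ResidueKey]],
    top_n: int = 5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Rank residue pairs by the change in optimal path length between two networks.

    For each (source, target): delta = optimal length in ``net_b`` minus
    optimal length in ``net_a`` (negative delta = communication shortened
    in b).  Returns the table sorted ascending by delta (unreachable
    pairs flagged, delta NaN, sorted last) plus per-residue participation
    counts over the ``top_n`` most-shortened pairs' optimal paths in
    ``net_b`` — the map of which residues carry the strengthened
    communication.
    """
    rows = []
    best_paths_b: dict[tuple, list] = {}
    for source, target in pairs:
        ps_a = shortest_paths(net_a, source, target, k=1)
        ps_b = shortest_paths(net_b, source, target, k=1)
        ok = ps_a.reachable and ps_b.reachable
        len_a = float(ps_a.lengths[0]) if ps_a.reachable else np.nan
        len_b = float(ps_b.lengths[0]) if ps_b.reachable else np.nan
        delta = len_b - len_a if ok else np.nan
        rel = delta / len_a if ok and len_a > 0 else np.nan
        rows.append({
            "source": source, "target": target,
            "length_a": len_a, "length_b": len_b,
            "delta": delta, "rel_delta": rel, "reachable": ok,
        })
        if ps_b.reachable:
            best_paths_b[(source, target)] = ps_b.paths[0]
    table = pd.DataFrame(rows).sort_values(
        "delta", na_position="last", kind="mergesort"
    ).reset_index(drop=True)

    counts: dict[ResidueKey, int] = {}
    shortened = table[table["reachable"] & (table["delta"] < 0)].head(top_n)
    for row in shortened.itertuples(index=False):
        for node in best_paths_b.get((row.source, row.target), []):
            counts[node] = counts.get(node, 0) + 1
    participation = pd.Series(counts, dtype=int).sort_values(ascending=False)
    return table, participation
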