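"""Synthetic-data generators for every pipeline input.

The toy system is a bead model of the real problem: a rigid core of
Cα-like beads, a metal site bead, and a mobile loop whose center of
mass sits either near the site (closed) or away from it (open).  The
generators plant known ground truth — state labels, mixing fractions,
correlation blocks, distance modes — so every downstream stage can be
tested as a parameter-recovery problem with no external data.

Default geometry is calibrated so that an equal-mixture pool reproduces
the loop-to-site distance moments of a realistic initial modelling pool
(mean 18.4 Å, s.d. 3.5 Å), keeping the synthetic world quantitatively
comparable to the real one.  Loop centers are placed at an exact radial
distance d + N(0, jitter_sd) from the site along a uniformly random
direction, so the requested moments are the true moments of the pool
(a 3-D positional jitter would bias the mean upward by ~sigma^2/d).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .docking import Pose, PoseSet
from .dynamics_network import Trajectory
from .saxs import SAXSProfile, TheoreticalCurve, debye_curve, ensemble_average_curve
from .structure_io import Atom, Conformer, ConformerEnsemble, Residue

logger = logging.getLogger(__name__)

__all__ = [
    "ToyProteinSpec",
    "NoiseModel",
    "make_two_state_ensemble",
    "simulate_saxs_profile",
    "simulate_correlated_trajectory",
    "simulate_pose_set",
]

_BOND = 3.8  # Cα-Cα virtual bond length, Å


@dataclass
class ToyProteinSpec:
    """Geometry of the bead-model protein with a two-state loop.

    ``closed_distance``/``open_distance`` are the loop-COM-to-site
    distances of the two states; ``jitter_sd`` is the per-model radial
    spread around each.  Defaults give an equal mixture the moments
    18.4 ± 3.5 Å.
    """

    n_core_residues: int = 40
    loop_residue_count: int = 12
    site_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    closed_distance: float = 15.05
    open_distance: float = 21.75
    jitter_sd: float = 1.0
    core_radius: float = 10.0

    def __post_init__(self) -> None:
        self.site_position = np.asarray(self.site_position, dtype=float)
        if not (self.open_distance > self.closed_distance > 0):
            raise ValueError("need open_distance > closed_distance > 0")
        if self.n_core_residues < 1 or self.loop_residue_count < 1:
            raise ValueError("residue counts must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        reach = self.core_radius + self.loop_residue_count * _BOND
        if self.open_distance + 3 * max(self.jitter_sd, 1e-9) > reach:
            raise ValueError(
                f"loop of {self.loop_residue_count} beads cannot reach "
                f"{self.open_distance:.1f} Å from the site (max reach {reach:.1f} Å)"
            )


@dataclass
class NoiseModel:
    """Multiplicative-plus-floor noise: sigma(s) = relative_sd * I(s) + floor."""

    relative_sd: float = 0.02
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.relative_sd < 0 or self.floor < 0:
            raise ValueError("noise parameters must be >= 0")


def _sphere_points(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _loop_ring(center: np.ndarray, normal: np.ndarray, m: int) -> np.ndarray:
    """m beads on a circle around ``center`` perpendicular to ``normal``.

    Consecutive beads are one virtual bond apart and the bead centroid is
    exactly ``center``.
    """
    if m == 1:
        return center[None, :]
    radius = _BOND / (2.0 * np.sin(np.pi / m))
    normal = normal / np.linalg.norm(normal)
    # any vector not parallel to normal
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = 2.0 * np.pi * np.arange(m) / m
    return center + radius * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)


def make_two_state_ensemble(
    spec: ToyProteinSpec,
    n_models: int,
    f_closed: float,
    seed: int,
) -> tuple[ConformerEnsemble, list[str]]:
    """Two-state loop pool with exactly round(f_closed * n_models) closed models.

    The rigid core (identical across models) is a bead shell of radius
    ``core_radius`` around the site; the loop is a bead ring whose center
    of mass is placed at radial distance d_state + N(0, jitter_sd) from
    the site in a uniformly random direction.  Returns the ensemble and
    the ground-truth label list ("closed"/"open", in model order).
    """
    if not 0.0 <= f_closed <= 1.0:
        raise ValueError("f_closed must be in [0, 1]")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    n_closed = round(f_closed * n_models)
    labels = ["closed"] * n_closed + ["open"] * (n_models - n_closed)
    rng.shuffle(labels)

    core = spec.site_position + spec.core_radius * _sphere_points(spec.n_core_residues)
    conformers = []
    for m, label in enumerate(labels, start=1):
        d_target = spec.closed_distance if label == "closed" else spec.open_distance
        d = max(d_target + rng.normal(0.0, spec.jitter_sd), 0.1)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        loop_center = spec.site_position + d * direction
        loop = _loop_ring(loop_center, direction, spec.loop_residue_count)

        residues = [
            Residue(chain="A", number=i + 1, name="GLY",
                    atoms=[Atom(name="CA", element="C", position=p)])
            for i, p in enumerate(core)
        ]
        residues += [
            Residue(chain="A", number=spec.n_core_residues + 1 + i, name="GLY",
                    atoms=[Atom(name="CA", element="C", position=p)])
            for i, p in enumerate(loop)
        ]
        residues.append(
            Residue(chain="A", number=999, name="CU",
                    atoms=[Atom(name="CU", element="Cu",
                                position=spec.site_position.copy(), het=True)])
        )
        conformers.append(Conformer(model_id=m, residues=residues))
    return ConformerEnsemble(conformers=conformers), labels


def simulate_saxs_profile(
    ens: ConformerEnsemble,
    weights: np.ndarray | None,
    s_grid: np.ndarray,
    noise: NoiseModel,
    seed: int,
) -> SAXSProfile:
    """Noisy experimental-style profile of a weighted conformer mixture.

    The noiseless intensity is the weighted Debye average over the pool;
    sigma(s) = relative_sd * I(s) + floor and the stored intensity is
    perturbed by Gaussian(0, sigma).  With a zero noise model the profile
    equals the forward curve exactly (sigma is stored as a tiny positive
    number to keep chi-square defined).
    """
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.all(weights == 0):
            raise ValueError("weights are all zero")
    curves = [debye_curve(c, s_grid) for c in ens]
    mean = ensemble_average_curve(curves, weights)
    return _noisify(mean, noise, seed)


def _noisify(curve: TheoreticalCurve, noise: NoiseModel, seed: int) -> SAXSProfile:
    rng = np.random.default_rng(seed)
    sigma = noise.relative_sd * np.abs(curve.intensity) + noise.floor
    intensity = curve.intensity.copy()
    live = sigma > 0
    intensity[live] += rng.normal(0.0, sigma[live])
    tiny = 1e-9 * max(np.abs(curve.intensity).max(), 1.0)
    return SAXSProfile(s=curve.s.copy(), intensity=intensity,
                       sigma=np.where(live, sigma, tiny))


def simulate_correlated_trajectory(
    base: Conformer,
    block_spec: list[tuple[list[int], float]],
    n_frames: int,
    amplitude_sd: float,
    seed: int,
    frame_interval: float = 1.8,
) -> Trajectory:
    """Trajectory with planted residue-residue displacement correlations.

    ``block_spec`` is a list of (residue positions, rho): the listed
    residues (0-based indices into ``base.residues``; blocks disjoint)
    get pairwise displacement correlation rho, everything else is
    independent.  Per-frame residue displacements are drawn from a
    zero-mean multivariate normal (per Cartesian axis) with standard
    deviation ``amplitude_sd``; positive semidefiniteness of the
    correlation matrix is enforced by eigenvalue clipping (logged when a
    repair exceeds numerical noise, rejected when the repair would alter
    requested correlations materially).
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    r = len(base.residues)
    corr = np.eye(r)
    seen: set[int] = set()
    for members, rho in block_spec:
        if abs(rho) > 1.0:
            raise ValueError(f"|rho| > 1 in block {members}")
        if seen.intersection(members):
            raise ValueError("correlation blocks must be disjoint")
        seen.update(members)
        for i in members:
            for j in members:
                if i != j:
                    corr[i, j] = rho

    evals, evecs = np.linalg.eigh(corr)
    worst = -evals.min() if evals.min() < 0 else 0.0
    if worst > 0.05:
        raise ValueError(
            f"correlation structure infeasible (needs eigenvalue repair of {worst:.3f}); "
            "note rho >= -1/(block size - 1) for a uniform negative block"
        )
    if worst > 1e-10:
        logger.info("nearest-PSD repair applied (smallest eigenvalue %.3e)", -worst)
    evals = np.clip(evals, 0.0, None)
    chol_like = evecs * np.sqrt(evals)  # corr = L @ L.T

    rng = np.random.default_rng(seed)
    disp = np.empty((n_frames, r, 3))
    for axis in range(3):
        g = rng.standard_normal((n_frames, r))
        disp[:, :, axis] = amplitude_sd * (g @ chol_like.T)

    frames = []
    for t in range(n_frames):
        residues = []
        for i, res in enumerate(base.residues):
            atoms = [
                Atom(name=a.name, element=a.element, position=a.position + disp[t, i],
                     occupancy=a.occupancy, adp=a.adp, het=a.het)
                for a in res.atoms
            ]
            residues.append(Residue(chain=res.chain, number=res.number, name=res.name,
                                    atoms=atoms, icode=res.icode))
        frames.append(Conformer(model_id=t + 1, residues=residues))
    return Trajectory(frames=frames, frame_interval=frame_interval)


def simulate_pose_set(
    n_poses: int,
    distance_mixture: list[tuple[float, float, float]],
    site: np.ndarray,
    seed: int,
    score_slope: float = 0.35,
    score_intercept: float = -11.0,
    score_sd: float = 0.4,
) -> PoseSet:
    """Docking-pose set with distances drawn from a Gaussian mixture.

    ``distance_mixture`` is a list of (mode Å, sd Å, weight) with weights
    on the simplex.  Each pose is a single-bead ligand at the sampled
    distance from ``site`` in a uniformly random direction; scores follow
    a distance-correlated linear model (closer poses bind more strongly)
    with Gaussian noise.  Negative sampled distances are rejected and
    redrawn (logged).
    """
    site = np.asarray(site, dtype=float)
    if n_poses < 0:
        raise ValueError("n_poses must be >= 0")
    modes = np.array([m for m, _, _ in distance_mixture])
    sds = np.array([s for _, s, _ in distance_mixture])
    w = np.array([x for _, _, x in distance_mixture], dtype=float)
    if np.any(modes <= 0) or np.any(sds < 0):
        raise ValueError("mixture modes must be positive and sds non-negative")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    poses = []
    rejected = 0
    for i in range(n_poses):
        comp = rng.choice(len(modes), p=w)
        d = rng.normal(modes[comp], sds[comp]) if sds[comp] > 0 else modes[comp]
        while d <= 0:
            rejected += 1
            d = rng.normal(modes[comp], sds[comp])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = site + d * direction
        score = score_intercept + score_slope * d + rng.normal(0.0, score_sd)
        poses.append(Pose(
            pose_id=f"pose{i:05d}",
            ligand_atoms=[Atom(name="C1", element="C", position=pos)],
            score=float(score),
        ))
    if rejected:
        logger.info("rejected and redrew %d negative distances", rejected)
    return PoseSet(poses=poses, receptor_sites={"site": site})
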