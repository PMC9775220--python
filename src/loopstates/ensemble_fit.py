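"""Loop-state inference against SAXS data.

The scientific core: a flexible active-site loop samples "open" and
"closed" conformations; each model in a pool is scored by the distance
from the loop center of mass to the catalytic metal site (and optionally
by the accessible surface of the site patch), classified open/closed,
and the experimental scattering curve is explained either by a genetic
subensemble selection over the pool or by a two-state population scan
mixing the state-average curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import center_of_mass, shrake_rupley_asa
from .saxs import (
    Chi2Result,
    SAXSProfile,
    TheoreticalCurve,
    chi2_discrepancy,
    ensemble_average_curve,
)
from .structure_io import ConformerEnsemble, select_subset

logger = logging.getLogger(__name__)

__all__ = [
    "StateLabels",
    "SubensembleSelection",
    "PopulationFit",
    "GAParams",
    "loop_site_distance",
    "site_patch_asa",
    "classify_states",
    "select_subensemble",
    "population_scan",
]


@dataclass
class StateLabels:
    """Per-conformer open/closed assignment with the metrics behind it."""

    labels: list[str]                      # "open" | "closed", one per conformer
    d_loop_site: np.ndarray                # Å
    boundary: float                        # Å; closed <=> d <= boundary
    patch_asa: np.ndarray | None = None    # Å², optional site-patch accessibility

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.d_loop_site):
            raise ValueError("one label per distance required")
        if np.any(self.d_loop_site < 0):
            raise ValueError("distances must be non-negative")

    @property
    def closed_fraction(self) -> float:
        return sum(l == "closed" for l in self.labels) / len(self.labels)

    def indices(self, state: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == state], dtype=int)


@dataclass
class SubensembleSelection:
    """A size-N_se multiset of pool members and the fit quality of its average curve."""

    member_indices: list[int]
    chi2: float
    scale: float

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass
class PopulationFit:
    """Chi-square versus closed-state fraction over a [0, 1] grid."""

    f_grid: np.ndarray
    chi2_of_f: np.ndarray
    best_f: float
    best_chi2: float


@dataclass
class GAParams:
    """Genetic-algorithm hyperparameters; the seed is mandatory."""

    seed: int
    population: int = 100
    generations: int = 200
    mutation_rate: float = 0.1
    allow_repeats: bool = True


def loop_site_distance(
    ens: ConformerEnsemble,
    loop_range: tuple[int, int],
    site_atom: tuple[str, int, str],
    chain: str | None = None,
) -> np.ndarray:
    """Distance (Å) from the loop's mass-weighted center of mass to a site atom.

    ``site_atom`` is (chain, residue number, atom name).  One value per
    conformer, in pool order.
    """
    loop = select_subset(ens, chain=chain, residue_range=loop_range)
    out = np.empty(len(ens))
    site_chain, site_num, site_name = site_atom
    for i, (conf, loop_conf) in enumerate(zip(ens, loop)):
        site = conf.residue(site_chain, site_num).atom(site_name).position
        com = center_of_mass([a for a in loop_conf.atoms()])
        out[i] = float(np.linalg.norm(com - site))
    return out


def site_patch_asa(
    ens: ConformerEnsemble,
    site_atom: tuple[str, int, str],
    radius: float = 12.0,
    probe_radius: float = 1.4,
    n_points: int = 240,
) -> np.ndarray:
    """Accessible surface (Å²) of the residue patch around a site atom.

    The patch is every residue with any heavy atom within ``radius`` Å of
    the site atom (the site's own residue excluded); its ASA is summed
    from a whole-model accessibility calculation, one value per conformer.
    """
    site_chain, site_num, site_name = site_atom
    out = np.empty(len(ens))
    for i, conf in enumerate(ens):
        site_pos = conf.residue(site_chain, site_num).atom(site_name).position
        table = shrake_rupley_asa(conf, probe_radius=probe_radius, n_points=n_points)
        total = 0.0
        for res, asa in zip(conf.residues, table["asa_A2"]):
            if res.key == (site_chain, site_num, ""):
                continue
            heavy = [a for a in res.atoms if a.element.strip().upper() != "H"]
            if not heavy:
                continue
            dmin = min(np.linalg.norm(a.position - site_pos) for a in heavy)
            if dmin <= radius:
                total += asa
        out[i] = total
    return out


def _two_means_split(d: np.ndarray, max_iter: int = 200) -> float | None:
    """Deterministic 1-D 2-means: means start at min/max; returns the midpoint boundary.

    None signals a degenerate split (a cluster emptied or no spread).
    """
    lo, hi = float(d.min()), float(d.max())
    if hi - lo <= 0:
        return None
    m1, m2 = lo, hi
    for _ in range(max_iter):
        closed = d <= 0.5 * (m1 + m2)
        if closed.all() or (~closed).all():
            return None
        n1, n2 = float(d[closed].mean()), float(d[~closed].mean())
        if n1 == m1 and n2 == m2:
            break
        m1, m2 = n1, n2
    return 0.5 * (m1 + m2)


def classify_states(
    distances: np.ndarray,
    patch_asa: np.ndarray | None = None,
    method: str = "two-component split",
    threshold: float | None = None,
) -> StateLabels:
    """Label each conformer open or closed from its loop-to-site distance.

    ``method="threshold"`` uses the explicit ``threshold`` (Å);
    ``"two-component split"`` finds the boundary as the midpoint between
    the two 1-D cluster means (2-means initialised at min/max, so the
    result is deterministic and order-invariant).  A degenerate pool
    (unimodal to the point of an empty cluster, or a single model) falls
    back to a threshold at the median with a logged warning.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("distances must be a non-empty 1-D vector")
    if method == "threshold":
        if threshold is None:
            raise ValueError("threshold method requires an explicit threshold")
        boundary = float(threshold)
    elif method == "two-component split":
        boundary = _two_means_split(d) if d.size >= 2 else None
        if boundary is None:
            boundary = float(np.median(d))
            logger.warning(
                "degenerate distance distribution: falling back to a threshold "
                "at the median (%.2f Å)", boundary,
            )
    else:
        raise ValueError(f"unknown classification method {method!r}")
    labels = ["closed" if x <= boundary else "open" for x in d]
    return StateLabels(labels=labels, d_loop_site=d, boundary=boundary,
                       patch_asa=patch_asa)


def _chi2_many(intensities: np.ndarray, exp: SAXSProfile) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised fitted-scale reduced chi-square for a stack of curves."""
    w = 1.0 / exp.sigma ** 2
    denom = (w * intensities ** 2).sum(axis=1)
    mu = np.where(denom > 0, (w * exp.intensity * intensities).sum(axis=1) / denom, 1.0)
    resid = (exp.intensity[None, :] - mu[:, None] * intensities) / exp.sigma[None, :]
    return (resid ** 2).sum(axis=1) / (len(exp) - 1), mu


def select_subensemble(
    pool_curves: list[TheoreticalCurve],
    exp: SAXSProfile,
    n_se: int,
    ga_params: GAParams,
) -> SubensembleSelection:
    """Genetic selection of the size-``n_se`` multiset whose average curve best fits.

    Fitness is the (negative) fitted-scale reduced chi-square of the
    uniform average of the chosen curves.  Single-point crossover,
    per-gene mutation, tournament selection and elitism; the initial
    population is seeded with the best single model and a greedy forward
    selection, so the result never fits worse than those baselines.
    Fully reproducible given the mandatory seed.
    """
    if n_se < 1:
        raise ValueError("n_se must be >= 1")
    if not pool_curves:
        raise ValueError("empty pool")
    n_pool = len(pool_curves)
    if not ga_params.allow_repeats and n_se > n_pool:
        raise ValueError("n_se exceeds pool size and repeats are forbidden")
    pool = np.stack([c.intensity for c in pool_curves])
    for c in pool_curves:
        if c.s.shape != exp.s.shape or np.any(np.abs(c.s - exp.s) > 1e-9):
            raise ValueError("pool curves are not on the experimental grid")

    def evaluate(population: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        avg = pool[population].mean(axis=1)
        return _chi2_many(avg, exp)

    if n_pool == 1:
        chi2, mu = evaluate(np.zeros((1, n_se), dtype=int))
        return SubensembleSelection(member_indices=[0] * n_se,
                                    chi2=float(chi2[0]), scale=float(mu[0]))

    rng = np.random.default_rng(ga_params.seed)
    single_chi2, _ = _chi2_many(pool, exp)
    best_single = int(np.argmin(single_chi2))

    # greedy forward construction (with replacement) as a strong seed individual
    greedy: list[int] = []
    running = np.zeros(pool.shape[1])
    for k in range(n_se):
        cand = (running[None, :] * k + pool) / (k + 1)
        chi2_c, _ = _chi2_many(cand, exp)
        pick = int(np.argmin(chi2_c))
        greedy.append(pick)
        running = (running * k + pool[pick]) / (k + 1)

    pop_size = max(ga_params.population, 4)
    population = rng.integers(0, n_pool, size=(pop_size, n_se))
    population[0] = best_single
    population[1] = greedy

    best_ind, best_chi2, best_mu = None, np.inf, 1.0
    for _ in range(ga_params.generations):
        chi2, mu = evaluate(population)
        gen_best = int(np.argmin(chi2))
        if chi2[gen_best] < best_chi2:
            best_chi2 = float(chi2[gen_best])
            best_mu = float(mu[gen_best])
            best_ind = population[gen_best].copy()
        # binary tournaments
        a = rng.integers(0, pop_size, size=pop_size)
        b = rng.integers(0, pop_size, size=pop_size)
        winners = np.where((chi2[a] <= chi2[b])[:, None], population[a], population[b])
        # single-point crossover on consecutive pairs
        children = winners.copy()
        if n_se > 1:
            for i in range(0, pop_size - 1, 2):
                cut = int(rng.integers(1, n_se))
                children[i, cut:] = winners[i + 1, cut:]
                children[i + 1, cut:] = winners[i, cut:]
        # per-gene mutation
        mask = rng.random(children.shape) < ga_params.mutation_rate
        children[mask] = rng.integers(0, n_pool, size=int(mask.sum()))
        children[0] = best_ind  # elitism
        population = children

    chi2, mu = evaluate(population)
    gen_best = int(np.argmin(chi2))
    if chi2[gen_best] < best_chi2:
        best_chi2, best_mu, best_ind = float(chi2[gen_best]), float(mu[gen_best]), population[gen_best].copy()

    if not ga_params.allow_repeats and len(set(best_ind.tolist())) < n_se:
        # repair: replace duplicates by best unused singles
        used = set()
        repaired = []
        order = np.argsort(single_chi2)
        for idx in best_ind.tolist():
            if idx in used:
                idx = next(i for i in order.tolist() if i not in used)
            used.add(idx)
            repaired.append(int(idx))
        best_ind = np.array(repaired)
        res = _chi2_many(pool[best_ind].mean(axis=0)[None, :], exp)
        best_chi2, best_mu = float(res[0][0]), float(res[1][0])

    return SubensembleSelection(
        member_indices=sorted(int(i) for i in best_ind),
        chi2=best_chi2,
        scale=best_mu,
    )


def population_scan(
    closed_curve: TheoreticalCurve,
    open_curve: TheoreticalCurve,
    exp: SAXSProfile,
    f_step: float = 0.01,
) -> PopulationFit:
    """Chi-square of the two-state mixture f*closed + (1-f)*open versus experiment.

    The scan covers f in [0, 1] inclusive at ``f_step`` resolution with a
    fitted scale at each point; ties at the minimum resolve to the larger
    closed fraction (logged).
    """
    if not 0 < f_step <= 0.5:
        raise ValueError("f_step must be in (0, 0.5]")
    n = int(round(1.0 / f_step))
    f_grid = np.linspace(0.0, 1.0, n + 1)
    chi2 = np.empty(f_grid.shape)
    for i, f in enumerate(f_grid):
        mix = ensemble_average_curve([closed_curve, open_curve],
                                     weights=np.array([f, 1.0 - f]))
        chi2[i] = chi2_discrepancy(exp, mix, fit_scale=True).chi2
    best_idx = len(chi2) - 1 - int(np.argmin(chi2[::-1]))  # ties -> larger f
    if (chi2 == chi2[best_idx]).sum() > 1:
        logger.info("population scan: tie at the minimum; reporting the larger f")
    return PopulationFit(
        f_grid=f_grid,
        chi2_of_f=chi2,
        best_f=float(f_grid[best_idx]),
        best_chi2=float(chi2[best_idx]),
    )
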