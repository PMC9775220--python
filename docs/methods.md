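# Methods

This note records the models, conventions and numerical choices behind
`loopstates`, and what the synthetic benchmarks do and do not demonstrate.

## Scattering model

Theoretical intensities come from the Debye equation over point
scatterers, I(s) = Σᵢⱼ fᵢfⱼ sin(s·rᵢⱼ)/(s·rᵢⱼ), with the i = j terms
contributing fᵢ², so I(s→0) = (Σfᵢ)². Form factors default to **uniform**
(f = 1 per heavy atom) with an optional per-element electron-count mode;
there is no hydration-shell or excluded-volume correction. This is
deliberate: every fitting benchmark in the package is self-consistent
(data simulated with the same forward model), so the ensemble-inference
machinery — not solvent modelling — is what is being tested. Absolute
χ² values against real beamline data would require a solvent-corrected
predictor and are out of scope.

Above 2000 atoms the pair distances are histogrammed on 0.01 Å bins
before the sine sum, bounding the relative error well below 10⁻³ on the
bead models used here (tested) while making the cost linear in the number
of s points. Momentum transfer is inverse-Å everywhere internally; the
reader converts inverse-nm on input because mixed units are the dominant
real-world failure mode for this file format.

The discrepancy score is the reduced chi-square with the 1/(K−1)
normalisation (the EOM/CRYSOL convention; 1/K is available) and the
analytic weighted-least-squares scale factor
μ = Σ(I_exp·I_theo/σ²)/Σ(I_theo²/σ²). Guinier R_g comes from a weighted
fit of ln I against s², with the admissible window s·R_g < 1.3 determined
iteratively from the fitted R_g itself. P(r) is solved as non-negative
least squares on a histogram basis with a second-difference smoothness
penalty; the end bins are pinned to zero and, when no λ is supplied, λ is
taken at the L-curve corner (closest point to the origin in normalised
log-residual/log-roughness coordinates).

## Ensemble inference

Each pool model is summarised by the distance from the loop's
mass-weighted centre of mass to the site metal atom, optionally
complemented by the accessible surface of the site patch (all residues
with a heavy atom within 12 Å of the site atom; the radius is a pinned,
configurable choice since no standard definition exists). Open/closed
classification uses a deterministic one-dimensional 2-means (means
initialised at the extremes, boundary at the midpoint of the converged
means); degenerate pools fall back to a median threshold with a logged
warning. No fixed distance threshold is hard-coded, because the physically
meaningful boundary depends on the system; an explicit threshold override
exists.

Subensemble selection is a genetic algorithm over size-N_se multisets
(repeats allowed, per ensemble-optimisation convention; a no-repeat flag
exists): fitness is −χ² of the uniform average of the members' curves,
with tournament selection, single-point crossover, per-gene mutation
(default rate 0.1), elitism, population 100 and 200 generations, and a
mandatory seed. The initial population is seeded with the best single
model and a greedy forward construction, which in practice guarantees the
result fits no worse than the full-pool uniform average. The objective is
pure χ² at fixed N_se — no ensemble-size penalty — with N_se scanned
externally when needed; this is the simplest objective consistent with
the selection task, and it is pinned rather than guessed.

The two-state population scan evaluates χ²(f) for the mixture
f·closed + (1−f)·open on an inclusive [0, 1] grid (default step 0.01)
with a fitted scale at each point; ties at the minimum resolve to the
larger closed fraction, logged.

## Trajectory statistics and networks

RMSF, DCC and PCA operate on one representative atom per residue (Cα by
name, first atom as fallback, so single-bead toy residues work).
Alignment is two-pass: superpose every frame on the running mean, twice.
DCC is the scalar dot-product correlation of 3-D displacement vectors —
the standard definition for Cα displacement analysis — not per-coordinate
correlation; zero-variance residues get zeroed rows with unit diagonal.
PCA eigendecomposes the 3R×3R aligned covariance; rank deficiency is
allowed and simply yields zero trailing eigenvalues.

The residue network places nodes at mass-weighted residue centres of mass
of the mean structure, connects pairs within a 4.5 Å centre-of-mass
cutoff, and weights edges −ln|C_ij| (configurable 1−|C_ij|), so stronger
correlation means shorter communication distance. Contacts are evaluated
on the trajectory-mean structure, not frame-averaged. Suboptimal paths
use Yen's loopless k-shortest algorithm (via networkx) with k ≤ 15 and
lexicographic tie-breaking; a brute-force simple-path enumeration serves
as the test oracle. Variant-versus-reference comparison ranks pairs by
the change in optimal path length (absolute Δℓ by default; the relative
change is also emitted) and maps per-residue participation over the five
most-shortened pairs' optimal paths in the variant network.

## Structure metrics

Superposition is Kabsch via SVD with reflection correction and optional
weights; collinear inputs are rejected as degenerate. Accessible surface
area is Shrake–Rupley with probe 1.4 Å and 960 quasi-uniform
(golden-spiral) points per atom by default, on a bundled Bondi-type
radius set; relative percentages divide by a bundled per-residue-type
theoretical maximum (Gly-X-Gly reference, backbone + side chain
combined). Exact parity with grid-based crystallographic ASA programs is
not expected; parameters are pinned and configurable, and an independent
implementation (biotite) cross-checks the calculation in the tests.
Minimum residue–residue distances default to heavy atoms, matching
hydrogen-free crystal structures; all-atom and side-chain-heavy scopes
are available because published per-residue distances rarely state their
convention. The Matthews coefficient is V_M = V_cell/(Z·M) with solvent
content (1 − 1.23/V_M)·100.

## Synthetic data: what it emulates, and what it does not

The toy system is a bead model: a rigid core shell (40 beads, radius
10 Å) around the site metal, plus a mobile loop ring of 12 beads whose
centre of mass sits at distance d from the site. Loop placement draws
d = d_state + N(0, jitter_sd) and a uniform random direction, placing the
centre at that **exact radial distance** — a 3-D positional jitter would
bias the mean distance upward by ≈σ²/d, and the exact-radial construction
makes the requested moments the true pool moments. Default state
distances (15.05 / 21.75 Å, jitter 1 Å) are calibrated so an equal
mixture reproduces the 18.4 ± 3.5 Å loop-to-site distribution of a
realistic initial modelling pool. Exactly round(f·n) models are closed.

Trajectories plant block correlation structure by sampling residue
displacements from a multivariate normal per Cartesian axis (feasibility
requires ρ ≥ −1/(m−1) for a uniform block of m residues; small negative
eigenvalues are clipped with a log message, larger ones rejected). Pose
sets draw site distances from a Gaussian mixture with uniform random
directions and a distance-correlated linear score model.

Passing the recovery benchmarks therefore demonstrates that the
inference machinery is correct and well-calibrated **under its own
forward model**: real data add solvent scattering, inter-atomic form
factors, correlated noise, force-field bias and anharmonic dynamics that
no bead model represents. The benchmarks say nothing about those effects.

## Problem sizes and determinism

The acceptance script uses pools of 120–2500 models (2500 only where no
scattering is computed), 100–200-point s grids, 2000-frame trajectories
of 16 residues and 2000 docking poses — sizes at which each stage runs in
seconds on one core while keeping sampling error an order of magnitude
inside the recovery tolerances. Every stochastic stage takes an explicit
seed; generators are bit-reproducible given the seed.

## Known limitations

- No solvent/excluded-volume scattering corrections (see above).
- PDB input only (no mmCIF); altlocs collapse to highest occupancy.
- The ASA reference-maximum table covers the 20 standard residues;
  relative percentages are NaN for other residue types.
- Network contacts use the mean structure; transiently formed contacts
  that vanish in the mean are not represented.
- The population scan assumes exactly two states; a continuum of
  intermediates will be projected onto the closed/open axis.
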