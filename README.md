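# loopstates

Ensemble analysis of flexible active-site loops from small-angle X-ray
scattering, simulation trajectories and docking output.

Many metalloenzymes carry a flexible "gate-keeper" loop — in multicopper
oxidases a methionine-rich omega loop — over the catalytic metal site.
Whether that loop is **open** or **closed** controls substrate access and,
over the course of directed evolution, can flip an enzyme's substrate
preference. `loopstates` implements the computational toolchain used to
characterise such equilibria:

- **SAXS ensemble fitting.** Theoretical scattering of a model by the Debye
  equation, I(s) = Σᵢⱼ fᵢfⱼ sin(s·rᵢⱼ)/(s·rᵢⱼ); discrepancy against an
  experimental profile by the reduced chi-square
  χ² = (1/(K−1)) Σⱼ [(I_exp(sⱼ) − μ·I_theo(sⱼ))/σ(sⱼ)]² with the analytic
  least-squares scale μ; genetic selection of the N_se-member subensemble
  whose average curve minimises χ²; Guinier R_g and P(r) by regularised
  indirect transform.
- **Open/closed state inference.** Per-model distance from the loop centre
  of mass to the site metal (d_loop–site), deterministic two-component
  classification, and a two-state population scan χ²(f) over mixtures
  f·closed + (1−f)·open.
- **Trajectory statistics and residue networks.** RMSF, Cα-covariance PCA,
  dynamic cross-correlation C_ij = ⟨Δrᵢ·Δrⱼ⟩/√(⟨|Δrᵢ|²⟩⟨|Δrⱼ|²⟩), and a
  residue network with centre-of-mass contacts (4.5 Å) and edge weight
  −ln|C_ij|, on which optimal and up to 15 suboptimal communication paths
  are found and compared between variants.
- **Structure and docking metrics.** Kabsch superposition RMSD,
  Shrake–Rupley accessible surface area, minimum residue–residue
  distances, Matthews coefficient/solvent content, and docking-pose
  distance histograms with per-bin score summaries.
- **Synthetic data.** Bead-model generators that plant known ground truth
  (mixing fractions, correlation blocks, distance modes) so every stage is
  testable as a parameter-recovery problem with no downloads.

## Worked example

```python
import numpy as np
import loopstates as ls
from loopstates.synthetic import _noisify

spec = ls.ToyProteinSpec(closed_distance=12.0, open_distance=24.0, jitter_sd=1.0)
s = np.linspace(0.01, 0.35, 100)
ens, labels = ls.make_two_state_ensemble(spec, 120, 0.5, seed=1)
curves = [ls.debye_curve(c, s) for c in ens]
closed = ls.ensemble_average_curve([c for c, l in zip(curves, labels) if l == "closed"])
open_ = ls.ensemble_average_curve([c for c, l in zip(curves, labels) if l == "open"])

mix = ls.ensemble_average_curve([closed, open_], weights=np.array([0.7, 0.3]))
exp = _noisify(mix, ls.NoiseModel(relative_sd=0.02), seed=2)
fit = ls.population_scan(closed, open_, exp)
print(f"recovered best_f = {fit.best_f:.2f}  (chi2 = {fit.best_chi2:.2f})")
```

prints

```
recovered best_f = 0.70  (chi2 = 0.91)
```

i.e. the scan recovers the planted 70% closed population exactly at the
grid resolution, and the χ² near 1 says the two-state model explains the
curve to within the simulated experimental noise. The `examples/`
directory has one short script per capability (population scan,
subensemble selection, trajectory networks, docking histograms,
structure metrics), each printing the numbers it computes and what they
mean. A thin CLI (`loopstates --help`) exposes the same stages as
subcommands, each writing a JSON manifest sufficient to re-run it.

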