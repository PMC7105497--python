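# loopmsm

Markov state model (MSM) analysis of loop open/close kinetics in membrane
proteins, exercised end to end on a synthetic two-loop Langevin surrogate.

Tetraspanins close a central cavity with two extracellular loops — a short
one (SEL) and a large one (LEL) — and the slow conformational exchange
between **closed**, **semi-open** and **open** loop arrangements is the
object of study. Direct simulation of such exchange is out of reach for one
long trajectory, so the field's standard workflow aggregates many short
trajectories and models the kinetics with an MSM. `loopmsm` implements that
workflow as a tested, reusable library:

- **Featurization** — frames are described by Gaussian RMSD-kernel features
  `exp(−RMSD(x, rⱼ)²/2σ²)` (σ = 0.5 Å) against 50 reference structures chosen
  as the medoids of a k-medoid (PAM) clustering of the trajectory pool.
- **Discretization** — k-means into 500 microstates (Euclidean metric in
  kernel-feature space).
- **MSM estimation** — transitions counted at lag τ = 20 ns (200 frames at
  the 0.1 ns stride), restricted to the largest strongly connected state set,
  and estimated under detailed balance (reversible maximum likelihood).
  Diagnostics: implied timescales `tᵢ = −τ / ln λᵢ(τ)`, Chapman–Kolmogorov
  tests `T(τ)^f` vs `T(fτ)`, and metastable-state counting by the largest
  relative spectral gap.
- **Model selection** — 3-fold cross-validation with the GMRQ (generalized
  matrix Rayleigh quotient) objective: the sum of the leading eigenvalues of
  the held-out transition matrix under the train-fold state definition.
- **Adaptive sampling** — superposed-coordinate features → PCA (15 dims) →
  k-means (2000 clusters) → 100 randomly chosen clusters seed 100 ns restart
  simulations from the frames nearest the cluster centers.
- **Reconstruction & observables** — long pseudo-trajectories (20 μs, 100 μs,
  15 ms) are synthesized by sampling the MSM chain and emitting stored frames
  of the visited states; the SEL–LEL contact
  `(1 − (d/d₀)ⁿ)/(1 − (d/d₀)ᵐ)` with d₀ = 8 Å, n = 6, m = 12 (equal to
  `1/(1+(d/d₀)⁶)` since m = 2n) is reported as a time course, a distribution,
  and a closed/semi-open/open classification.

Because real trajectory data of this kind is not redistributable, the
`synthetic` module generates trajectories with the same statistical
structure: a gap coordinate diffusing on a three-well landscape (overdamped
Langevin), embedded as 3-D bead frames of an SEL/LEL pair. The exact
relaxation timescales and well-to-well transition matrix of the surrogate
are computed from the grid-discretised diffusion generator, giving every
pipeline stage a ground-truth recovery test.

## Worked example

```python
from loopmsm import RunConfig
from loopmsm.pipeline import generate_pool, analyze_pool

cfg = RunConfig.test_scale(seed=1)          # desk-size variant of the design
pool, log, _ = generate_pool(cfg)           # 24 x 250 ns + one adaptive round
result = analyze_pool(pool, cfg, campaign_log=log)

print(result.msm.summary())
print("state fractions over the reconstructed 100 us trajectory:")
for state, frac in result.state_fractions["100us"].items():
    print(f"  {state:<10}{frac:.3f}")
```

prints

```
Markov State Model Results
==============================================
states (active set)                        100
lag time [ns]                           20.000
reversible                                True
counting                               sliding
total counts                             58200
metastable states                            3
----------------------------------------------
  i      eigenvalue    timescale [ns]
  2        0.886253            165.63
  3        0.574573             36.09
  4       -0.090230                --
  5        0.070802              7.55
  6        0.068560              7.46
==============================================
state fractions over the reconstructed 100 us trajectory:
  closed    0.577
  semi-open 0.178
  open      0.245
```

The fitted MSM finds **three** metastable states, and its two slow implied
timescales (165.6 ns and 36.1 ns here) recover the surrogate's exact
relaxation times (158.0 ns and 37.1 ns from the diffusion generator) from
6.5 μs of aggregate sampling. The state fractions classify the reconstructed
100 μs contact series with the package's thresholds (closed ≥ 0.6,
open ≤ 0.2, printed in every report header).

A CLI mirrors the stages (`loopmsm simulate | featurize | cluster | msm |
gmrq | adapt | reconstruct | report | pipeline`); e.g.

```sh
loopmsm pipeline --scale test --seed 1 --out run/
```

writes the transition matrix, stationary distribution, implied timescales,
contact series/distribution CSVs, a JSON report and courtesy plots, each
with a JSON metadata sidecar (config hash, seed, versions).

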