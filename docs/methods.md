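# Methods

This note records the models, estimators and numerical choices behind
`loopmsm`, and what its synthetic benchmark does and does not establish.

## The surrogate system

The object being emulated is the slow open/close motion of a pair of
extracellular loops (SEL and LEL). The surrogate reduces this to one
collective coordinate, the inter-loop gap `g` (Å), governed by overdamped
(Brownian) Langevin dynamics

    g ← g − Δt·U′(g)/γ + sqrt(2·kT·Δt/γ)·ξ,   ξ ~ N(0, 1),

with a Gaussian-mixture well landscape

    U(g) = −kT·log Σᵢ wᵢ·N(g; cᵢ, sᵢ),   wᵢ = exp(depthᵢ)·sᵢ.

An overdamped rather than underdamped integrator is used because only the
stationary and kinetic structure matters downstream and it has one fewer
parameter. The mixture form gives smooth gradients and a closed-form
stationary density `exp(−U/kT)/Z = Σᵢ wᵢ N(g; cᵢ, sᵢ)/Σᵢ wᵢ`, which the
tests exploit directly (a single well is exactly Gaussian).

Default landscape (`default_surrogate`): three wells at **4, 9 and 14 Å**
(closed, semi-open, open), widths 0.8 Å, depths 3.4/2.8/3.1 kT, kT = 1,
friction γ = 1 kT·ns/Å² (diffusion constant D = 1 Å²/ns). These values were
fixed once, to a regime a kinetics study would call realistic for desk-scale
work: barriers of ~4.5 kT give slowest relaxations of **158.0 ns and
37.1 ns** (exact, see below) and well populations 0.44/0.24/0.32 — clearly
metastable at the 20 ns analysis lag, yet crossed often enough that a few
microseconds of aggregate sampling contains tens of slow transitions. The
barrier heights of the real system are unknown; these are testability
choices, not fitted values.

Each gap value is embedded as a 12-bead frame: a rigid SEL template, the
LEL template translated by `g` along the gap axis, plus i.i.d. isotropic
Gaussian jitter (sd 0.15 Å) per bead per frame. The templates place one
apex bead of each loop exactly on the gap axis, so with zero jitter the
minimum SEL–LEL distance equals `g` identically — the affine map the
embedding tests assert. Jitter is uncorrelated (no collective loop flexing)
to keep the RMSD structure analytically predictable.

Integration uses Δt = 0.01 ns with frames recorded every 0.1 ns (10
substeps), mirroring the analysis stride; Δt is comfortably below the
stability limit `s²γ/kT = 0.64 ns` of the stiffest well. Divergence beyond a
configured bound raises with advice to reduce Δt.

### Exact ground truth from the generator

Rather than freezing simulated numbers, the ground truth is computed on
demand from the 1-D Smoluchowski generator discretised as a birth–death
chain on a 400-point grid with detailed-balance rates
`k(i→i±1) = (D/h²)·exp(−(U_j−U_i)/2kT)`. Symmetrising with the Boltzmann
weights makes the generator Hermitian; `eigh` then yields exact relaxation
rates (timescales = −1/λ), slow eigenfunctions, and — via `expm(τL)` — the
well-projected transition matrix at any lag. The brute-force consistency
test projects long simulations onto the exact slow eigenfunction and fits
the autocorrelation decay (unbiased per-lag normalisation; fit window
20–150 ns, beyond the 37 ns mode, averaged over 5 seeds), agreeing with the
generator timescale within 20%.

## Featurization and discretization

- **RMSD kernel.** Feature (i, j) = `exp(−RMSD(xᵢ, rⱼ)²/2σ²)`, σ = 0.5 Å,
  with minimum (superposed) RMSD. Superposition uses the Kabsch algorithm
  with the smallest singular value sign-corrected, so reflections are never
  returned; degenerate (collinear) point sets raise instead of silently
  reflecting. Batched RMSD against a reference stacks the 3×3 SVDs in one
  LAPACK call; the residual formula is replaced by direct transform
  application in the scalar path, where cancellation would otherwise limit
  accuracy near zero.
- **References by k-medoids.** PAM alternation (assign, then exhaustive
  in-cluster medoid search) on the pairwise-RMSD matrix, seeded
  k-means++-style on squared distances. The O(pool²) matrix is made
  tractable by striding the pool down to ≤ `max_pool` frames (default 2000)
  before selection; references remain genuine pool frames. The kernel
  transform is applied to the features that feed the 500-state k-means as
  well — clustering happens in kernel space.
- **k-means.** A hand-written Lloyd loop (k-means++ seeding, Euclidean
  metric) because the discretization contract pins behaviour an MSM
  pipeline depends on: empty clusters are reseeded to the farthest point so
  k stays fixed (the 500/2000 counts are structural), nearest-center ties
  resolve to the lowest index, and the objective is non-increasing.
  Defaults tol 1e-6 on the center shift, max_iter 300, recorded in output
  metadata.
- **PCA** (adaptive step, 15 components) uses the deterministic full-SVD
  solver; component signs are fixed by forcing each component's
  largest-magnitude loading positive, for reproducibility across linear
  algebra backends. Requests beyond the data rank raise.

## MSM estimation

Transitions are counted in sliding mode (every start offset; strided mode
available) and never across trajectory boundaries. The count graph is
restricted to its largest strongly connected component before estimation.
The default estimator is the reversible maximum-likelihood fixed point
`x_ij ← (c_ij + c_ji)/(c_i/x_i + c_j/x_j)`, iterated until the largest
update < 1e-10; plain row normalisation is available and serves as the
test oracle's starting point. Eigenvalues are sorted by modulus; complex
pairs (possible for non-reversible estimates) are excluded from implied
timescales with a flag rather than dropped silently.

**Metastable-state counting** takes the largest relative spectral gap
`(λᵢ − λᵢ₊₁)/λᵢ` among leading real eigenvalues, with a floor: only
eigenvalues ≥ 0.5 qualify as metastable relaxations (timescale ≥ τ/ln 2).
Without the floor, near-zero tail eigenvalues trivially maximise the
relative gap.

**GMRQ cross-validation** splits folds at whole-trajectory granularity with
a seeded shuffle (frames of one trajectory never straddle folds, avoiding
count leakage across the lag). Per fold, the featurizer and the cluster
centers are fit on the training trajectories only; the test score is the
sum of the `m` leading eigenvalues of the transition matrix estimated from
the held-out counts restricted to the train-defined active set. `m` defaults
to 5 and is logged in every result; the underlying study names the GMRQ
objective but not `m`. Reversibility of the published model is likewise
unstated; both are config-exposed with logged defaults.

**Reconstruction** samples the estimated chain and emits, per step, one
uniformly chosen stored frame of the visited state; each step spans one lag
time, so 5000 steps at 20 ns give a 100 μs pseudo-trajectory. States
without stored frames fail before sampling begins.

## Adaptive sampling

One round clusters the pooled trajectories (superposed coordinates → PCA →
k-means), draws `n_restarts` clusters uniformly **without replacement** —
the literal reading of "randomly selected", with no population weighting —
and restarts from the pool frame nearest each chosen center (never an
interpolation). Fresh per-restart noise seeds play the role of
Maxwell-distributed restart velocities in the overdamped setting. Round and
restart seeds derive from the master seed by a counter
(`seed + 1000·(round+1) + restart`). The number of rounds is config-exposed
(default 1; the emulated protocol describes a single pass). Scaled-down
defaults (50 clusters, 10 restarts) ship alongside the full-scale ones
(2000/100). The benchmark comparing adaptive restarts with one long run of
equal budget uses 40–50 ns segments: restart segments must be long enough
to cross local barriers (~37 ns here) for the strategy to pay off, matching
the 100 ns restarts of the emulated design.

## Contact observable and state classification

`contact(d) = (1 − (d/d₀)ⁿ)/(1 − (d/d₀)ᵐ)`, d₀ = 8 Å, n = 6, m = 12. The
removable singularity at d = d₀ returns the analytic limit n/m (= 1/2 here)
rather than an epsilon-shifted evaluation; elsewhere the form is evaluated
as `expm1(n·log x)/expm1(m·log x)`, which is cancellation-free near the
cutoff and matches the exact simplification `1/(1+(d/d₀)ⁿ)` (valid whenever
m = 2n) to better than 1e-12 across a dense grid. `d` is the minimum
distance over **all** inter-group bead pairs (not centroids); which atoms
enter this minimum in the emulated protocol is unstated, and all beads is
the literal reading.

The closed/semi-open/open classification thresholds (closed ≥ 0.6,
open ≤ 0.2, boundaries to the extreme classes) are this package's
operationalisation — the named conformations are defined structurally, not
by a numeric contact boundary — and are printed in every report header.

## Problem sizes

Full-scale defaults reproduce the emulated study design: 100 initial 100 ns
trajectories plus one adaptive round of 100 × 100 ns (≈ 20 μs aggregate,
0.1 ns stride), 50 references, 500 microstates, lag 20 ns, reconstructions
of 20 μs / 100 μs / 15 ms. The `test_scale()` configuration used by the
test suite and the acceptance script keeps the same design at desk size:
24 × 250 ns plus 10 × 50 ns adaptive restarts (≈ 6.5 μs), 20 references
(pool strided to ≤ 1200 for medoid selection), 100 microstates, the same
20 ns lag, and 20 μs / 100 μs / 1 ms reconstructions. At this size the
three-state structure and both slow timescales are recovered comfortably
(within ~5% at the documented seed; the across-seed spread is a few tens of
percent, consistent with ~40 slow-transition events in the pool).

## What the synthetic benchmark does and does not show

Passing tests establish that every stage implements its contract: the
estimators recover known generators at the expected O(1/√N) rate, the
variational score ranks discretizations correctly, reconstruction preserves
stationarity, and the full chain identifies the metastable structure of a
system whose kinetics are known exactly. They do not establish anything
about force-field accuracy, convergence of real MD sampling, the
million-fold timescale separations of all-atom systems, correlated loop
flexibility (the jitter is i.i.d.), or featurization choices among real
alternatives (e.g. backbone dihedrals, which the bead surrogate cannot
express). Periodic-boundary distances are likewise out of scope — the
surrogate is non-periodic.

## Known limitations

- k-medoid selection subsamples large pools; with very rugged landscapes a
  rare state could be missed among the references (the kernel features of
  such frames would still differ from all references, so the k-means step
  can isolate them).
- The reversible MLE assumes the trimmed count graph reflects equilibrium
  exchange; strongly non-equilibrium pools (e.g. immediately after an
  aggressive adaptive round) bias π toward the restart distribution.
  Population estimates from reconstruction inherit that bias; timescales
  are more robust.
- Implied timescales near the lag (t ≲ τ) are systematically unreliable;
  the metastability floor (λ ≥ 0.5) encodes exactly this.
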