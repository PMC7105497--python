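"""Synthetic two-loop dynamics standing in for all-atom MD.

The surrogate reduces the open/close motion of a tetraspanin's short and large
extracellular loops (SEL, LEL) to one collective coordinate: the gap ``g``
between the loops, in angstroms.  ``g`` diffuses on a multi-well free-energy
landscape under overdamped Langevin dynamics; each gap value is then embedded
as a 3-D bead frame (rigid SEL template, LEL template translated by ``g`` along
a gap axis, plus isotropic jitter) so that every downstream stage — RMSD
featurization, clustering, MSM estimation, contact observables — is exercised
on coordinates, not on the hidden coordinate.

The gap potential is a Gaussian-mixture well landscape,

    U(g) = -kT log sum_i w_i N(g; c_i, s_i),   w_i = exp(depth_i) * s_i,

whose stationary density exp(-U/kT)/Z is available in closed form for tests,
and whose exact relaxation spectrum is computable by discretising the 1-D
overdamped generator on a grid (:func:`reference_timescales`).  The default
surrogate has three wells — closed, semi-open and open — along the gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .trajectory import Trajectory

__all__ = [
    "PotentialSpec",
    "LoopModelSpec",
    "DiscreteTrajectory",
    "GroundTruth",
    "sample_discrete_chain",
    "simulate_langevin_gap",
    "simulate_langevin_gap_batch",
    "embed_loop_frames",
    "default_surrogate",
    "reference_timescales",
    "projected_transition_matrix",
    "well_of_gap",
    "FRAME_DT_NS",
]

#: frame stride written into trajectory metadata, ns (the analysis subsampling)
FRAME_DT_NS = 0.1


@dataclass(frozen=True)
class PotentialSpec:
    """Gaussian-mixture well landscape for the gap coordinate.

    ``wells`` is a list of (center [A], depth [kT], width [A]) tuples with
    strictly increasing centers.  ``depth`` is the well depth on the kT scale:
    for well-separated wells, U(c_i) ~ -kT * depth_i up to a common constant.
    """

    wells: tuple[tuple[float, float, float], ...]
    kT: float = 1.0
    description: str = ""

    def __post_init__(self) -> None:
        wells = tuple((float(c), float(d), float(s)) for c, d, s in self.wells)
        object.__setattr__(self, "wells", wells)
        if len(wells) < 1:
            raise ValueError("at least one well required")
        centers = [c for c, _, _ in wells]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("well centers must be strictly increasing")
        if any(s <= 0 for _, _, s in wells):
            raise ValueError("well widths must be positive")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    @property
    def centers(self) -> np.ndarray:
        return np.array([c for c, _, _ in self.wells])

    def _mixture(self, g):
        g = np.asarray(g, dtype=float)
        p = np.zeros_like(g)
        dp = np.zeros_like(g)
        for c, d, s in self.wells:
            w = np.exp(d) * s
            comp = w * np.exp(-0.5 * ((g - c) / s) ** 2) / (s * np.sqrt(2 * np.pi))
            p = p + comp
            dp = dp + comp * (c - g) / s**2
        return p, dp

    def energy(self, g):
        """U(g) in the same units as kT."""
        p, _ = self._mixture(g)
        return -self.kT * np.log(p)

    def gradient(self, g):
        """dU/dg in kT-units per angstrom."""
        p, dp = self._mixture(g)
        return -self.kT * dp / p

    def stationary_density(self, g):
        """Boltzmann density exp(-U/kT), normalised (closed form: the mixture)."""
        p, _ = self._mixture(g)
        total = sum(np.exp(d) * s for _, d, s in self.wells)
        return p / total

    def barriers(self) -> np.ndarray:
        """Positions of the energy maxima between adjacent well centers."""
        out = []
        for (c0, _, _), (c1, _, _) in zip(self.wells, self.wells[1:]):
            gg = np.linspace(c0, c1, 2001)
            out.append(gg[int(np.argmax(self.energy(gg)))])
        return np.array(out)


@dataclass(frozen=True)
class LoopModelSpec:
    """Coarse bead templates for the SEL and LEL loops and the gap embedding."""

    sel_template: np.ndarray
    lel_template: np.ndarray
    jitter_sd: float = 0.15
    gap_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        sel = np.asarray(self.sel_template, dtype=float)
        lel = np.asarray(self.lel_template, dtype=float)
        for name, t in (("sel_template", sel), ("lel_template", lel)):
            if t.ndim != 2 or t.shape[1] != 3 or t.shape[0] < 3:
                raise ValueError(f"{name} must be (>=3, 3)")
            if np.linalg.matrix_rank(t - t.mean(axis=0)) < 2:
                raise ValueError(f"{name} is degenerate (collinear beads)")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        axis = np.asarray(self.gap_axis, dtype=float)
        nrm = np.linalg.norm(axis)
        if nrm == 0:
            raise ValueError("gap_axis must be non-zero")
        object.__setattr__(self, "sel_template", sel)
        object.__setattr__(self, "lel_template", lel)
        object.__setattr__(self, "gap_axis", axis / nrm)

    @property
    def n_beads_sel(self) -> int:
        return self.sel_template.shape[0]

    @property
    def n_beads_lel(self) -> int:
        return self.lel_template.shape[0]

    @property
    def groups(self) -> tuple[str, ...]:
        return ("SEL",) * self.n_beads_sel + ("LEL",) * self.n_beads_lel


@dataclass
class DiscreteTrajectory:
    """Sequence of microstate labels with the time per step in ns."""

    labels: np.ndarray
    lag_unit: float = FRAME_DT_NS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D sequence")
        if np.any(self.labels < 0):
            raise ValueError("state labels must be non-negative")

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class GroundTruth:
    """Oracle package for parameter-recovery tests.

    ``transition_matrix`` is row-stochastic (here: the exact grid propagator of
    the gap diffusion, coarse-grained onto the wells at the MSM lag);
    ``timescales`` are the exact relaxation times of the diffusion in ns,
    sorted descending; ``state_of_frame`` optionally labels frames of a
    concrete trajectory with their well.
    """

    transition_matrix: np.ndarray
    timescales: np.ndarray
    state_of_frame: np.ndarray | None = None
    lag_ns: float | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition_matrix rows must sum to 1")
        self.transition_matrix = T
        ts = np.asarray(self.timescales, dtype=float)
        if np.any(np.diff(ts) > 0):
            raise ValueError("timescales must be sorted descending")
        self.timescales = ts


def _validate_stochastic(T: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"transition matrix must be square, got {T.shape}")
    if np.any(T < -atol):
        raise ValueError("transition matrix has negative entries")
    rowsum = T.sum(axis=1)
    bad = np.flatnonzero(np.abs(rowsum - 1.0) > atol)
    if bad.size:
        raise ValueError(
            f"row {bad[0]} of transition matrix sums to {rowsum[bad[0]]:.12g}, not 1"
        )
    return T


def sample_discrete_chain(
    T: np.ndarray,
    n_steps: int,
    seed: int,
    initial: int | np.ndarray | None = None,
    lag_unit: float = FRAME_DT_NS,
) -> DiscreteTrajectory:
    """Sample a Markov chain of ``n_steps`` states from row-stochastic ``T``.

    ``initial`` is a state index, a probability vector, or None (uniform).
    Identical (T, n_steps, seed, initial) give identical output.
    """
    T = _validate_stochastic(T)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    k = T.shape[0]
    rng = np.random.default_rng(seed)
    if initial is None:
        state = int(rng.integers(k))
    elif np.ndim(initial) == 0:
        state = int(initial)
        if not 0 <= state < k:
            raise ValueError(f"initial state {state} out of range")
    else:
        p0 = np.asarray(initial, dtype=float)
        if p0.shape != (k,) or not np.isclose(p0.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must be a length-k probability vector")
        state = int(rng.choice(k, p=p0 / p0.sum()))
    cdf = np.cumsum(T, axis=1)
    cdf[:, -1] = 1.0
    u = rng.random(n_steps)
    labels = np.empty(n_steps, dtype=int)
    labels[0] = state
    for t in range(1, n_steps):
        state = int(np.searchsorted(cdf[state], u[t]))
        labels[t] = state
    return DiscreteTrajectory(labels=labels, lag_unit=lag_unit)


def simulate_langevin_gap_batch(
    potential: PotentialSpec,
    n_steps: int,
    dt: float,
    friction: float,
    seed: int,
    x0: np.ndarray,
    record_stride: int = 1,
    bound: float = 1e3,
) -> np.ndarray:
    """Overdamped (Brownian) dynamics for a batch of independent walkers.

    Euler-Maruyama update ``g <- g - dt U'(g)/gamma + sqrt(2 kT dt/gamma) xi``
    with xi standard normal, applied to every walker each step.  Records every
    ``record_stride``-th step; returns shape (n_recorded, n_walkers) where
    n_recorded = n_steps // record_stride.

    Raises if any walker exceeds ``bound`` in absolute value (diverging
    integration; reduce dt).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if friction <= 0:
        raise ValueError("friction must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if record_stride < 1 or n_steps % record_stride:
        raise ValueError("record_stride must divide n_steps")
    g = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    rng = np.random.default_rng(seed)
    noise_scale = np.sqrt(2.0 * potential.kT * dt / friction)
    n_rec = n_steps // record_stride
    out = np.empty((n_rec, g.size))
    for i in range(n_rec):
        for _ in range(record_stride):
            g += -dt * potential.gradient(g) / friction + noise_scale * rng.standard_normal(g.size)
        if np.any(np.abs(g) > bound):
            raise FloatingPointError(
                "gap diverged beyond the configured bound; use a smaller dt"
            )
        out[i] = g
    return out


def simulate_langevin_gap(
    potential: PotentialSpec,
    n_steps: int,
    dt: float,
    friction: float,
    seed: int,
    x0: float,
    bound: float = 1e3,
) -> np.ndarray:
    """Single-walker overdamped gap trajectory; see :func:`simulate_langevin_gap_batch`."""
    return simulate_langevin_gap_batch(
        potential, n_steps, dt, friction, seed, np.array([float(x0)]), 1, bound
    )[:, 0]


def embed_loop_frames(gaps: np.ndarray, spec: LoopModelSpec, seed: int) -> Trajectory:
    """Embed a gap series as 3-D bead frames.

    Frame t = [SEL template; LEL template + g_t * gap_axis], plus i.i.d.
    isotropic Gaussian jitter of sd ``spec.jitter_sd`` on every bead.
    """
    gaps = np.asarray(gaps, dtype=float)
    if not np.all(np.isfinite(gaps)):
        raise ValueError("gaps contain non-finite values")
    n = gaps.size
    nb = spec.n_beads_sel + spec.n_beads_lel
    coords = np.empty((n, nb, 3))
    coords[:, : spec.n_beads_sel] = spec.sel_template
    coords[:, spec.n_beads_sel :] = (
        spec.lel_template[None, :, :] + gaps[:, None, None] * spec.gap_axis
    )
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(seed)
        coords += rng.normal(scale=spec.jitter_sd, size=coords.shape)
    return Trajectory(coords, spec.groups, dt=FRAME_DT_NS, meta={"embed_seed": seed})


def reference_timescales(
    potential: PotentialSpec,
    friction: float = 1.0,
    g_range: tuple[float, float] | None = None,
    n_grid: int = 400,
    n_timescales: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact relaxation times of the gap diffusion, by grid discretisation.

    The overdamped generator is discretised as a nearest-neighbour jump chain
    on a uniform grid with detailed-balance rates
    ``k(i -> i+-1) = (D/h^2) exp(-(U_j - U_i)/(2 kT))``, D = kT/friction.
    The chain is symmetrised with the Boltzmann weights and diagonalised;
    timescales are -1/lambda_k (ns) for the non-stationary eigenvalues, sorted
    descending.

    Returns (timescales, grid, stationary_weights).
    """
    if g_range is None:
        c = potential.centers
        widths = np.array([s for _, _, s in potential.wells])
        g_range = (c[0] - 5 * widths[0], c[-1] + 5 * widths[-1])
    grid = np.linspace(*g_range, n_grid)
    h = grid[1] - grid[0]
    U = potential.energy(grid) / potential.kT
    D = potential.kT / friction
    up = (D / h**2) * np.exp(-(U[1:] - U[:-1]) / 2.0)  # i -> i+1
    dn = (D / h**2) * np.exp(-(U[:-1] - U[1:]) / 2.0)  # i+1 -> i
    pi = np.exp(-(U - U.min()))
    pi /= pi.sum()
    # symmetrised generator: S_ij = sqrt(pi_i/pi_j) L_ij is symmetric
    sym_off = np.sqrt(up * dn)
    S = np.zeros((n_grid, n_grid))
    idx = np.arange(n_grid - 1)
    S[idx, idx + 1] = sym_off
    S[idx + 1, idx] = sym_off
    diag = np.zeros(n_grid)
    diag[:-1] -= up
    diag[1:] -= dn
    S[np.arange(n_grid), np.arange(n_grid)] = diag
    evals = scipy.linalg.eigh(S, eigvals_only=True)
    evals = np.sort(evals)[::-1]  # ~0 first, then negative
    rates = -evals[1 : n_timescales + 1]
    ts = 1.0 / rates
    return ts, grid, pi


def reference_slow_modes(
    potential: PotentialSpec,
    friction: float = 1.0,
    g_range: tuple[float, float] | None = None,
    n_grid: int = 400,
    n_modes: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slow right eigenfunctions of the gap diffusion on the grid.

    Returns (grid, modes, timescales) where ``modes[k]`` is the right
    eigenfunction of the k-th non-stationary relaxation (k = 0 slowest),
    normalised to unit stationary-weighted norm.  Projecting a trajectory
    onto a mode isolates that relaxation: its autocorrelation decays as a
    single exponential with the paired timescale.
    """
    if g_range is None:
        c = potential.centers
        widths = np.array([s for _, _, s in potential.wells])
        g_range = (c[0] - 5 * widths[0], c[-1] + 5 * widths[-1])
    grid = np.linspace(*g_range, n_grid)
    h = grid[1] - grid[0]
    U = potential.energy(grid) / potential.kT
    D = potential.kT / friction
    up = (D / h**2) * np.exp(-(U[1:] - U[:-1]) / 2.0)
    dn = (D / h**2) * np.exp(-(U[:-1] - U[1:]) / 2.0)
    pi = np.exp(-(U - U.min()))
    pi /= pi.sum()
    sym_off = np.sqrt(up * dn)
    S = np.zeros((n_grid, n_grid))
    idx = np.arange(n_grid - 1)
    S[idx, idx + 1] = sym_off
    S[idx + 1, idx] = sym_off
    diag = np.zeros(n_grid)
    diag[:-1] -= up
    diag[1:] -= dn
    S[np.arange(n_grid), np.arange(n_grid)] = diag
    evals, evecs = scipy.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    modes = np.empty((n_modes, n_grid))
    for k in range(n_modes):
        phi = evecs[:, k + 1] / np.sqrt(pi)  # right eigenfunction of L
        phi /= np.sqrt(np.sum(pi * phi**2))
        modes[k] = phi
    ts = 1.0 / (-evals[1 : n_modes + 1])
    return grid, modes, ts


def projected_transition_matrix(
    potential: PotentialSpec,
    lag_ns: float,
    friction: float = 1.0,
    n_grid: int = 400,
) -> np.ndarray:
    """Exact well-to-well transition matrix of the gap diffusion at a lag.

    Computes the grid propagator exp(lag * L) and coarse-grains it onto the
    wells (basins split at the inter-well energy maxima), weighting by the
    stationary distribution.  This is the projected (not Markovian-closed)
    transition matrix the MSM estimates at that lag.
    """
    ts, grid, pi = reference_timescales(potential, friction, n_grid=n_grid)
    h = grid[1] - grid[0]
    U = potential.energy(grid) / potential.kT
    D = potential.kT / friction
    up = (D / h**2) * np.exp(-(U[1:] - U[:-1]) / 2.0)
    dn = (D / h**2) * np.exp(-(U[:-1] - U[1:]) / 2.0)
    L = np.zeros((n_grid, n_grid))
    idx = np.arange(n_grid - 1)
    L[idx, idx + 1] = up
    L[idx + 1, idx] = dn
    L[np.arange(n_grid), np.arange(n_grid)] = -L.sum(axis=1)
    P = scipy.linalg.expm(lag_ns * L)
    basins = well_of_gap(potential, grid)
    k = len(potential.wells)
    T = np.zeros((k, k))
    for a in range(k):
        wa = pi * (basins == a)
        flux = wa @ P
        T[a] = np.array([flux[basins == b].sum() for b in range(k)]) / wa.sum()
    T /= T.sum(axis=1, keepdims=True)
    return T


def well_of_gap(potential: PotentialSpec, gaps) -> np.ndarray:
    """Assign gap values to wells: basins split at the inter-well energy maxima."""
    edges = potential.barriers()
    return np.searchsorted(edges, np.asarray(gaps, dtype=float))


def _default_templates() -> LoopModelSpec:
    # SEL: apex bead at the origin, ring of 5 beads 1 A below; LEL mirrored
    # above, so the apex pair lies exactly on the gap axis and the minimum
    # SEL-LEL distance equals the gap for any non-negative gap.
    ang = 2 * np.pi * np.arange(5) / 5
    ring = np.column_stack([1.5 * np.cos(ang), 1.5 * np.sin(ang), np.zeros(5)])
    sel = np.vstack([[0.0, 0.0, 0.0], ring - [0, 0, 1.0]])
    lel = np.vstack([[0.0, 0.0, 0.0], ring + [0, 0, 1.0]])
    return LoopModelSpec(sel_template=sel, lel_template=lel, jitter_sd=0.15)


#: default three-well landscape: closed / semi-open / open gaps (A, kT, A)
DEFAULT_WELLS = ((4.0, 3.4, 0.8), (9.0, 2.8, 0.8), (14.0, 3.1, 0.8))
DEFAULT_FRICTION = 1.0  # kT * ns / A^2, i.e. D = 1 A^2/ns
DEFAULT_LAG_NS = 20.0


def default_surrogate(
    n_grid: int = 400,
) -> tuple[PotentialSpec, LoopModelSpec, GroundTruth]:
    """The versioned default surrogate: three metastable wells along the gap.

    Wells at 4, 9 and 14 A model the closed, semi-open and open loop
    arrangements.  The ground truth (exact relaxation times and the
    well-projected transition matrix at the 20 ns analysis lag) is computed
    from the grid-discretised diffusion generator, not from simulation.
    """
    potential = PotentialSpec(
        wells=DEFAULT_WELLS,
        kT=1.0,
        description="three-well SEL-LEL gap landscape (closed / semi-open / open)",
    )
    loops = _default_templates()
    ts, _, _ = reference_timescales(potential, DEFAULT_FRICTION, n_grid=n_grid)
    T = projected_transition_matrix(potential, DEFAULT_LAG_NS, DEFAULT_FRICTION, n_grid)
    truth = GroundTruth(
        transition_matrix=T,
        timescales=np.sort(ts)[::-1],
        lag_ns=DEFAULT_LAG_NS,
    )
    return potential, loops, truth
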