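"""Markov state model estimation, validation and trajectory reconstruction.

The model is a discrete-state, discrete-lag Markov chain estimated from
discretized trajectories: transitions are counted at a lag time tau (default
20 ns, i.e. 200 frames at the 0.1 ns stride), the count matrix is restricted
to its largest strongly connected component, and the transition matrix is
estimated either by row normalisation or (default) by the reversible
maximum-likelihood estimator under detailed balance.  Diagnostics follow
standard MSM practice: implied timescales t_i = -tau / ln lambda_i(tau) and
their lag-independence, the Chapman-Kolmogorov test T(tau)^f vs T(f tau),
metastable-state counting by the largest relative spectral gap, and GMRQ
(generalized matrix Rayleigh quotient) cross-validation — the sum of the
leading held-out eigenvalues under a train-fold state definition — for
hyperparameter selection.

Long pseudo-trajectories are reconstructed by sampling the estimated chain
and emitting, for each visited state, one stored trajectory frame of that
state; each step spans one lag time.

Organised statsmodels-style: :class:`MarkovStateModel` is built from discrete
trajectories and ``fit()`` returns an :class:`MSMResults` carrying the
estimates and diagnostics; the module-level functions are the underlying
primitives and remain public.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components

from .synthetic import DiscreteTrajectory, FRAME_DT_NS

__all__ = [
    "CountMatrix",
    "ITSTable",
    "GMRQResult",
    "ReconstructedTrajectory",
    "MarkovStateModel",
    "MSMResults",
    "count_matrix",
    "trim_to_connected",
    "transition_matrix",
    "stationary_distribution",
    "eigenvalues_sorted",
    "implied_timescales",
    "ck_test",
    "count_metastable",
    "split_folds",
    "score_msm",
    "gmrq_cross_validate",
    "synthesize_trajectory",
    "frames_by_state",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Transition counts at a lag, with the surviving original state ids."""

    counts: np.ndarray
    lag: int
    counting_mode: str = "sliding"
    active_set: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.active_set is None:
            self.active_set = np.arange(self.counts.shape[0])
        else:
            self.active_set = np.asarray(self.active_set, dtype=int)

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


@dataclass
class ITSTable:
    """Implied timescales per lag; invalid entries are NaN and flagged, not dropped."""

    lags_ns: np.ndarray
    timescales: np.ndarray  # (n_lags, k) ns
    valid: np.ndarray  # bool, same shape

    def __post_init__(self) -> None:
        self.lags_ns = np.asarray(self.lags_ns, dtype=float)
        self.timescales = np.asarray(self.timescales, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class GMRQResult:
    """Per-fold GMRQ train/test scores and the hyperparameter snapshot."""

    train_scores: np.ndarray
    test_scores: np.ndarray
    fold_valid: np.ndarray
    n_folds: int
    m_eigs: int
    params: dict = field(default_factory=dict)

    @property
    def mean_test_score(self) -> float:
        ok = self.fold_valid
        if not np.any(ok):
            raise ValueError("no valid folds")
        return float(np.mean(self.test_scores[ok]))


@dataclass
class ReconstructedTrajectory:
    """MSM-synthesized pseudo-trajectory: states, emitted frames, time base.

    ``frame_refs`` holds one (trajectory index, frame index) row per step;
    each step spans one lag time, so the total span is n_steps * lag_ns.
    """

    states: np.ndarray
    frame_refs: np.ndarray
    lag_ns: float
    seed: int

    @property
    def n_steps(self) -> int:
        return self.states.size

    @property
    def span_ns(self) -> float:
        return self.n_steps * self.lag_ns

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.lag_ns

    def to_trajectory(self, pool):
        """Materialise coordinates by looking the emitted frames up in ``pool``."""
        from .trajectory import Trajectory

        coords = np.stack(
            [pool[ti].coords[fi] for ti, fi in self.frame_refs]
        )
        return Trajectory(
            coords, pool[0].groups, dt=self.lag_ns, meta={"reconstructed": True}
        )


# ---------------------------------------------------------------------------
# counting and estimation


def _as_label_arrays(dtrajs) -> list[np.ndarray]:
    if isinstance(dtrajs, DiscreteTrajectory):
        dtrajs = [dtrajs]
    elif isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    elif isinstance(dtrajs, (list, tuple)) and len(dtrajs) and np.isscalar(dtrajs[0]):
        dtrajs = [dtrajs]
    return [
        np.asarray(d.labels if isinstance(d, DiscreteTrajectory) else d, dtype=int)
        for d in dtrajs
    ]


def count_matrix(dtrajs, lag: int, mode: str = "sliding", n_states: int | None = None) -> CountMatrix:
    """Count transitions (s_t, s_{t+lag}) within each trajectory.

    ``sliding`` counts every start offset t; ``strided`` counts t = 0, lag,
    2 lag, ...  Counts never cross trajectory boundaries.  Raises when no
    trajectory is longer than the lag.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError(f"unknown counting mode {mode!r}")
    arrs = _as_label_arrays(dtrajs)
    if n_states is None:
        n_states = int(max(a.max() for a in arrs)) + 1
    C = np.zeros((n_states, n_states))
    any_pairs = False
    for a in arrs:
        if a.size <= lag:
            continue
        src = a[:-lag]
        dst = a[lag:]
        if mode == "strided":
            src, dst = src[::lag], dst[::lag]
        np.add.at(C, (src, dst), 1.0)
        any_pairs = True
    if not any_pairs:
        raise ValueError(f"no trajectory longer than lag={lag}: cannot count transitions")
    return CountMatrix(counts=C, lag=lag, counting_mode=mode)


def trim_to_connected(C: CountMatrix) -> CountMatrix:
    """Restrict to the largest strongly connected component of the count graph.

    The component with the most total counts wins ties in size; the surviving
    original state ids are recorded in ``active_set``.
    """
    adj = scipy.sparse.csr_matrix(C.counts > 0)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    best, best_key = None, None
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        key = (members.size, C.counts[np.ix_(members, members)].sum())
        if best is None or key > best_key:
            best, best_key = members, key
    if best is None or best.size == 0:
        raise ValueError("count matrix has no connected component")
    sub = C.counts[np.ix_(best, best)]
    return CountMatrix(
        counts=sub,
        lag=C.lag,
        counting_mode=C.counting_mode,
        active_set=C.active_set[best],
    )


def _reversible_mle(C: np.ndarray, tol: float = 1e-10, max_iter: int = 10000) -> np.ndarray:
    """Maximum-likelihood reversible transition matrix by fixed-point iteration.

    Iterates x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j) on the symmetric
    unnormalised flux matrix X (initialised at C + C^T) until the largest
    update falls below ``tol``; T = X / rowsums(X) then satisfies detailed
    balance exactly in the limit.
    """
    Csym = C + C.T
    X = Csym.copy()
    c_row = C.sum(axis=1)
    for _ in range(max_iter):
        x_row = X.sum(axis=1)
        q = c_row / x_row
        denom = q[:, None] + q[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            X_new = np.where(Csym > 0, Csym / denom, 0.0)
        delta = np.max(np.abs(X_new - X))
        X = X_new
        if delta < tol:
            break
    return X / X.sum(axis=1, keepdims=True)


def transition_matrix(C: CountMatrix, reversible: bool = True) -> np.ndarray:
    """Row-stochastic transition matrix from a connected count matrix.

    ``reversible=False`` gives plain row normalisation T_ij = C_ij / C_i;
    ``reversible=True`` (default) the maximum-likelihood estimate under
    detailed balance.  Raises on zero rows (trim to the connected set first).
    """
    counts = C.counts
    rows = counts.sum(axis=1)
    if np.any(rows == 0):
        raise ValueError("count matrix has a zero row; apply trim_to_connected first")
    if not reversible:
        return counts / rows[:, None]
    return _reversible_mle(counts)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution: the left unit-eigenvector, normalised to sum 1.

    Raises when T is reducible (no unique strictly positive solution).
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    if n == 1:
        return np.array([1.0])
    adj = scipy.sparse.csr_matrix(T > 0)
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("transition matrix is reducible; stationary distribution not unique")
    vals, vecs = scipy.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    pi /= pi.sum()
    return pi


def eigenvalues_sorted(T: np.ndarray, k: int | None = None) -> np.ndarray:
    """Eigenvalues of T sorted by modulus descending (complex preserved)."""
    vals = np.linalg.eigvals(np.asarray(T, dtype=float))
    order = np.argsort(-np.abs(vals))
    vals = vals[order]
    return vals if k is None else vals[:k]


def implied_timescales(
    dtrajs,
    lags,
    k_eigs: int = 5,
    reversible: bool = True,
    dt: float = FRAME_DT_NS,
    counting: str = "sliding",
) -> ITSTable:
    """Implied timescales t_i(tau) = -tau / ln lambda_i(tau), in ns.

    One MSM per lag (count, trim, estimate); the unit eigenvalue is skipped.
    Complex or non-positive eigenvalues yield NaN entries flagged invalid
    rather than being dropped.
    """
    lags = np.asarray(lags, dtype=int)
    ts = np.full((lags.size, k_eigs), np.nan)
    valid = np.zeros((lags.size, k_eigs), dtype=bool)
    for li, lag in enumerate(lags):
        C = trim_to_connected(count_matrix(dtrajs, int(lag), mode=counting))
        T = transition_matrix(C, reversible=reversible)
        vals = eigenvalues_sorted(T, k_eigs + 1)[1:]
        tau_ns = lag * dt
        for i, lam in enumerate(vals):
            if abs(lam.imag) < 1e-12 and 0.0 < lam.real < 1.0:
                ts[li, i] = -tau_ns / np.log(lam.real)
                valid[li, i] = True
    return ITSTable(lags_ns=lags * dt, timescales=ts, valid=valid)


def ck_test(dtrajs, lag: int, factors, reversible: bool = True) -> dict:
    """Chapman-Kolmogorov test: T(tau)^f against T estimated at f*tau.

    Returns per-factor max absolute element-wise deviation on the common
    active set; factors with insufficient data are flagged, not fatal.
    """
    factors = [int(f) for f in factors]
    if any(f < 2 for f in factors):
        raise ValueError("factors must be >= 2")
    C1 = trim_to_connected(count_matrix(dtrajs, lag))
    T1 = transition_matrix(C1, reversible=reversible)
    out = {"lag": lag, "factors": factors, "deviation": {}, "flagged": []}
    for f in factors:
        try:
            Cf = trim_to_connected(count_matrix(dtrajs, lag * f))
        except ValueError:
            out["flagged"].append(f)
            continue
        common, i1, i2 = np.intersect1d(
            C1.active_set, Cf.active_set, return_indices=True
        )
        if common.size == 0:
            out["flagged"].append(f)
            continue
        Tf = transition_matrix(Cf, reversible=reversible)
        Tpow = np.linalg.matrix_power(T1, f)
        out["deviation"][f] = float(
            np.max(np.abs(Tpow[np.ix_(i1, i1)] - Tf[np.ix_(i2, i2)]))
        )
    return out


def count_metastable(T: np.ndarray, top_k: int = 10, min_eigenvalue: float = 0.5) -> int:
    """Number of metastable states by the largest relative spectral gap.

    Takes the leading real eigenvalues lambda_1 = 1 >= lambda_2 >= ... and
    returns the index i maximising (lambda_i - lambda_{i+1}) / lambda_i among
    the top ``top_k`` candidates.  Only eigenvalues >= ``min_eigenvalue``
    qualify as metastable relaxations (the default 0.5 demands an implied
    timescale of at least lag / ln 2); without a floor, near-zero tail
    eigenvalues trivially maximise the relative gap.  Fewer than 2 states:
    returns 1.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    if n < 2:
        return 1
    vals = eigenvalues_sorted(T)
    real = np.array([v.real for v in vals if abs(v.imag) < 1e-9])
    real = np.clip(real, 0.0, None)
    lam = np.concatenate([real[: top_k + 1], [0.0]])
    best_i, best_gap = 1, -np.inf
    for i in range(1, min(top_k, lam.size - 1) + 1):
        if lam[i - 1] < min_eigenvalue:
            break
        gap = (lam[i - 1] - lam[i]) / lam[i - 1]
        if gap > best_gap:
            best_i, best_gap = i, gap
    return best_i


# ---------------------------------------------------------------------------
# GMRQ cross-validation


def split_folds(n_items: int, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Whole-trajectory fold split: a seeded shuffle cut into n_folds parts.

    Returns (train_indices, test_indices) per fold; frames of one trajectory
    never straddle folds, which avoids count leakage across the lag.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > n_items:
        raise ValueError(f"cannot split {n_items} trajectories into {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    parts = np.array_split(perm, n_folds)
    folds = []
    for i, test in enumerate(parts):
        train = np.concatenate([p for j, p in enumerate(parts) if j != i])
        folds.append((np.sort(train), np.sort(test)))
    return folds


def score_msm(train_dtrajs, test_dtrajs, lag: int, m_eigs: int = 5) -> tuple[float, float, bool]:
    """GMRQ-style scores for one fold.

    Train score: sum of the m_eigs leading eigenvalues of the train-estimated
    transition matrix.  Test score: same sum for the transition matrix
    estimated from the *test* counts restricted to the train-defined active
    set (largest connected subcomponent thereof).  Returns
    (train_score, test_score, valid); a fold whose test counts miss the train
    active set entirely is invalid.
    """
    Ctr = trim_to_connected(count_matrix(train_dtrajs, lag))
    Ttr = transition_matrix(Ctr, reversible=False)
    train_score = float(np.sum(np.real(eigenvalues_sorted(Ttr, min(m_eigs, Ttr.shape[0])))))
    n_states = int(Ctr.active_set.max()) + 1
    try:
        Cte_full = count_matrix(test_dtrajs, lag, n_states=max(
            n_states, max(int(np.max(a)) + 1 for a in _as_label_arrays(test_dtrajs))
        ))
    except ValueError:
        return train_score, np.nan, False
    sub = Cte_full.counts[np.ix_(Ctr.active_set, Ctr.active_set)]
    Cte = CountMatrix(counts=sub, lag=lag, active_set=Ctr.active_set)
    if Cte.counts.sum() == 0:
        return train_score, np.nan, False
    Cte = trim_to_connected(Cte)
    Tte = transition_matrix(Cte, reversible=False)
    test_score = float(np.sum(np.real(eigenvalues_sorted(Tte, min(m_eigs, Tte.shape[0])))))
    return train_score, test_score, True


def gmrq_cross_validate(
    trajs,
    pipeline,
    lag: int,
    n_folds: int = 3,
    m_eigs: int = 5,
    seed: int = 0,
) -> GMRQResult:
    """Cross-validated GMRQ score of a featurize-and-discretize pipeline.

    ``pipeline`` must expose ``fit(trajs) -> self`` and
    ``transform(trajs) -> list of label arrays``; per fold it is fit on the
    train trajectories only, both folds are discretized with the train-fold
    state definition, and :func:`score_msm` scores the held-out counts.
    """
    trajs = list(trajs)
    folds = split_folds(len(trajs), n_folds, seed)
    train_scores, test_scores, valid = [], [], []
    for train_idx, test_idx in folds:
        fitted = pipeline.fit([trajs[i] for i in train_idx])
        dtr = fitted.transform([trajs[i] for i in train_idx])
        dte = fitted.transform([trajs[i] for i in test_idx])
        tr, te, ok = score_msm(dtr, dte, lag, m_eigs)
        train_scores.append(tr)
        test_scores.append(te)
        valid.append(ok)
    return GMRQResult(
        train_scores=np.array(train_scores),
        test_scores=np.array(test_scores),
        fold_valid=np.array(valid, dtype=bool),
        n_folds=n_folds,
        m_eigs=m_eigs,
        params=getattr(pipeline, "params", {}),
    )


# ---------------------------------------------------------------------------
# reconstruction


def frames_by_state(labels: np.ndarray, provenance: np.ndarray) -> dict[int, np.ndarray]:
    """Map each state label to the (trajectory, frame) rows carrying it."""
    labels = np.asarray(labels, dtype=int)
    provenance = np.asarray(provenance, dtype=int)
    if labels.shape[0] != provenance.shape[0]:
        raise ValueError("labels and provenance lengths differ")
    return {
        int(s): provenance[labels == s] for s in np.unique(labels)
    }


def synthesize_trajectory(
    T: np.ndarray,
    frame_index: dict[int, np.ndarray],
    n_steps: int,
    seed: int,
    start=None,
    active_set: np.ndarray | None = None,
    lag_ns: float = 20.0,
) -> ReconstructedTrajectory:
    """Reconstruct a long pseudo-trajectory from an estimated MSM.

    Samples a discrete chain of ``n_steps`` from T (``start``: a state index
    in original labelling, a distribution over active states, or None for the
    stationary distribution) and emits one uniformly chosen stored frame of
    the visited state per step.  Each step spans one lag time.  Raises before
    sampling if any active state has no stored frame.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    if active_set is None:
        active_set = np.arange(n)
    active_set = np.asarray(active_set, dtype=int)
    for s in active_set:
        if int(s) not in frame_index or len(frame_index[int(s)]) == 0:
            raise ValueError(f"state {int(s)} has no stored frames to emit")
    rng = np.random.default_rng(seed)
    if start is None:
        p0 = stationary_distribution(T)
        state = int(rng.choice(n, p=p0))
    elif np.ndim(start) == 0:
        hits = np.flatnonzero(active_set == int(start))
        if hits.size == 0:
            raise ValueError(f"start state {start} not in the active set")
        state = int(hits[0])
    else:
        p0 = np.asarray(start, dtype=float)
        state = int(rng.choice(n, p=p0 / p0.sum()))
    cdf = np.cumsum(T, axis=1)
    cdf[:, -1] = 1.0
    states = np.empty(n_steps, dtype=int)
    refs = np.empty((n_steps, 2), dtype=int)
    for t in range(n_steps):
        if t > 0:
            state = int(np.searchsorted(cdf[state], rng.random()))
        states[t] = active_set[state]
        pool = frame_index[int(active_set[state])]
        refs[t] = pool[int(rng.integers(len(pool)))]
    return ReconstructedTrajectory(states=states, frame_refs=refs, lag_ns=lag_ns, seed=seed)


# ---------------------------------------------------------------------------
# Model / Results


class MarkovStateModel:
    """MSM specification bound to discretized trajectories.

    Parameters
    ----------
    dtrajs : list of DiscreteTrajectory or int arrays
        Microstate label sequences (one per trajectory).
    lag : int
        Lag time in frames (steps); with dt = 0.1 ns the default 200 is the
        20 ns analysis lag.
    dt : float
        Time per frame, ns.
    reversible : bool
        Estimate under detailed balance (maximum likelihood) when True,
        plain row normalisation when False.
    counting : {"sliding", "strided"}
    """

    def __init__(
        self,
        dtrajs,
        lag: int = 200,
        dt: float = FRAME_DT_NS,
        reversible: bool = True,
        counting: str = "sliding",
    ) -> None:
        self.dtrajs = _as_label_arrays(dtrajs)
        self.lag = int(lag)
        self.dt = float(dt)
        self.reversible = bool(reversible)
        self.counting = counting

    @classmethod
    def from_discretization(cls, disc, lag: int = 200, dt: float = FRAME_DT_NS, **kw):
        """Build from a :class:`~loopmsm.cluster.Discretization` with a recorded split."""
        return cls(disc.split_labels(), lag=lag, dt=dt, **kw)

    def fit(self) -> "MSMResults":
        C_full = count_matrix(self.dtrajs, self.lag, mode=self.counting)
        C = trim_to_connected(C_full)
        T = transition_matrix(C, reversible=self.reversible)
        pi = stationary_distribution(T)
        vals = eigenvalues_sorted(T)
        return MSMResults(model=self, count_model=C, transition_matrix_=T,
                          stationary_distribution_=pi, eigenvalues_=vals)


class MSMResults:
    """Fitted MSM: transition matrix, stationary distribution, spectrum, diagnostics."""

    def __init__(self, model, count_model, transition_matrix_, stationary_distribution_, eigenvalues_):
        self.model = model
        self.count_model = count_model
        self.transition_matrix = transition_matrix_
        self.stationary_distribution = stationary_distribution_
        self.eigenvalues = eigenvalues_
        self.active_set = count_model.active_set
        self.lag_ns = model.lag * model.dt

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def timescales(self, k: int = 5) -> np.ndarray:
        """Implied timescales in ns for the leading non-unit eigenvalues (NaN where undefined)."""
        vals = self.eigenvalues[1 : k + 1]
        out = np.full(len(vals), np.nan)
        for i, lam in enumerate(vals):
            if abs(lam.imag) < 1e-12 and 0.0 < lam.real < 1.0:
                out[i] = -self.lag_ns / np.log(lam.real)
        return out

    def n_metastable(self, top_k: int = 10) -> int:
        return count_metastable(self.transition_matrix, top_k=top_k)

    def ck_test(self, factors=(2, 3, 4)) -> dict:
        return ck_test(self.model.dtrajs, self.model.lag, factors,
                       reversible=self.model.reversible)

    def sample(self, n_steps: int, seed: int, start=None) -> DiscreteTrajectory:
        """Sample a state sequence from the fitted chain (original state labels)."""
        fake_index = {int(s): np.array([[0, 0]]) for s in self.active_set}
        rec = synthesize_trajectory(
            self.transition_matrix, fake_index, n_steps, seed, start=start,
            active_set=self.active_set, lag_ns=self.lag_ns,
        )
        return DiscreteTrajectory(labels=rec.states, lag_unit=self.lag_ns)

    def synthesize(
        self, frame_index: dict[int, np.ndarray], n_steps: int, seed: int, start=None
    ) -> ReconstructedTrajectory:
        """Reconstruct a pseudo-trajectory emitting stored frames; span = n_steps * lag."""
        return synthesize_trajectory(
            self.transition_matrix, frame_index, n_steps, seed, start=start,
            active_set=self.active_set, lag_ns=self.lag_ns,
        )

    def summary(self, k_timescales: int = 5) -> str:
        """Plain-text summary table of the fitted model."""
        ts = self.timescales(k_timescales)
        lines = [
            "Markov State Model Results",
            "=" * 46,
            f"{'states (active set)':<28}{self.n_states:>18d}",
            f"{'lag time [ns]':<28}{self.lag_ns:>18.3f}",
            f"{'reversible':<28}{str(self.model.reversible):>18}",
            f"{'counting':<28}{self.model.counting:>18}",
            f"{'total counts':<28}{self.count_model.counts.sum():>18.0f}",
            f"{'metastable states':<28}{self.n_metastable():>18d}",
            "-" * 46,
            f"{'i':>3}  {'eigenvalue':>14}  {'timescale [ns]':>16}",
        ]
        for i, t in enumerate(ts, start=2):
            lam = self.eigenvalues[i - 1]
            lam_str = f"{lam.real:.6f}" if abs(lam.imag) < 1e-12 else f"{lam:.4f}"
            t_str = f"{t:.2f}" if np.isfinite(t) else "--"
            lines.append(f"{i:>3}  {lam_str:>14}  {t_str:>16}")
        lines.append("=" * 46)
        return "\n".join(lines)
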