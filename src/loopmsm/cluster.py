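"""Microstate discretization by k-means in feature space.

A hand-rolled Lloyd loop (k-means++ seeding) is used rather than an external
estimator because the discretization contract pins details an MSM pipeline
depends on: empty clusters are repaired by reseeding to the farthest point
(keeping k fixed, since the 500/2000 cluster counts are structural), nearest-
center ties resolve to the lowest center index, and the objective is
non-increasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import pairwise_distances_argmin_min

from .featurize import FeatureMatrix

__all__ = ["Discretization", "kmeans", "assign"]


@dataclass
class Discretization:
    """k-means result: centers, per-frame labels, inertia and the run metadata."""

    centers: np.ndarray
    labels: np.ndarray
    inertia: float
    k: int
    seed: int
    params: dict = field(default_factory=dict)
    traj_lengths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("cluster centers contain non-finite values")
        if np.any(self.labels < 0) or np.any(self.labels >= self.k):
            raise ValueError("labels out of [0, k)")
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")

    def split_labels(self) -> list[np.ndarray]:
        """Labels split back into the source trajectories."""
        if self.traj_lengths is None:
            raise ValueError("no trajectory split recorded")
        return np.split(self.labels, np.cumsum(self.traj_lengths)[:-1])


def _as_values(F) -> np.ndarray:
    return F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=float)


def _chunked_assign(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-center labels and distances, chunked to bound memory."""
    n = X.shape[0]
    labels = np.empty(n, dtype=int)
    dists = np.empty(n)
    chunk = max(1, int(2e7 // max(centers.shape[0], 1)))
    for s in range(0, n, chunk):
        sl = slice(s, min(s + chunk, n))
        # argmin returns the first (lowest-index) minimiser: the tie rule
        labels[sl], dists[sl] = pairwise_distances_argmin_min(X[sl], centers)
    return labels, dists


def _kpp_seed(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[c] = X[rng.integers(n)]
            continue
        idx = int(rng.choice(n, p=d2 / total))
        centers[c] = X[idx]
        d2 = np.minimum(d2, np.sum((X - centers[c]) ** 2, axis=1))
    return centers


def kmeans(
    F,
    k: int,
    seed: int,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> Discretization:
    """Lloyd's k-means from k-means++ seeding, Euclidean metric.

    Iterates assignment / mean update until the largest center shift drops
    below ``tol`` or ``max_iter`` is reached.  An empty cluster is reseeded to
    the point farthest from its nearest center, keeping k fixed.  Determinism:
    identical (F, k, seed) give identical output.
    """
    X = _as_values(F)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available frames")
    rng = np.random.default_rng(seed)
    centers = _kpp_seed(X, k, rng)
    labels, dists = _chunked_assign(X, centers)
    for _ in range(max_iter):
        new_centers = centers.copy()
        for c in range(k):
            members = labels == c
            if not np.any(members):
                new_centers[c] = X[int(np.argmax(dists))]
            else:
                new_centers[c] = X[members].mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
        centers = new_centers
        labels, dists = _chunked_assign(X, centers)
        if shift < tol:
            break
    inertia = float(np.sum(dists**2))
    return Discretization(
        centers=centers,
        labels=labels,
        inertia=inertia,
        k=k,
        seed=seed,
        params={"max_iter": max_iter, "tol": tol},
        traj_lengths=getattr(F, "traj_lengths", None),
    )


def assign(F, centers: np.ndarray) -> np.ndarray:
    """Nearest-center label per frame (Euclidean; ties to the lowest index)."""
    X = _as_values(F)
    centers = np.asarray(centers, dtype=float)
    if X.shape[1] != centers.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match centers {centers.shape[1]}"
        )
    labels, _ = _chunked_assign(X, centers)
    return labels
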