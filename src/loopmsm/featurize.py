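"""Featurization: RMSD-kernel features, superposed coordinates, PCA.

The pipeline's selected featurization follows the Gaussian RMSD kernel: each
frame is described by ``exp(-RMSD(frame, ref_j)^2 / (2 sigma^2))`` against a
set of reference structures picked as the medoids of a k-medoid clustering of
the trajectory pool (PAM alternation on the pairwise-RMSD matrix).  Defaults
are sigma = 0.5 A and 50 references.  Superposed-coordinate features and a PCA
reduction (used by the adaptive-sampling round, default 15 components) are
also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from . import geometry
from .trajectory import Trajectory, concatenate_frames

__all__ = [
    "KernelFeaturizerParams",
    "ReferenceSet",
    "FeatureMatrix",
    "select_references",
    "rmsd_kernel_features",
    "calpha_position_features",
    "pca_reduce",
    "pairwise_rmsd_matrix",
]


@dataclass(frozen=True)
class KernelFeaturizerParams:
    """Width (A) of the Gaussian RMSD kernel and number of references."""

    sigma: float = 0.5
    reference_count: int = 50

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.reference_count < 1:
            raise ValueError("reference_count must be >= 1")


@dataclass
class ReferenceSet:
    """Reference frames (medoids) with provenance into the source pool."""

    structures: np.ndarray  # (k, n_beads, 3)
    source_frame_indices: np.ndarray  # (k, 2): (trajectory index, frame index)

    def __post_init__(self) -> None:
        self.structures = np.asarray(self.structures, dtype=float)
        if self.structures.ndim != 3 or self.structures.shape[2] != 3:
            raise ValueError("structures must be (k, n_beads, 3)")
        self.source_frame_indices = np.asarray(self.source_frame_indices, dtype=int)

    @property
    def k(self) -> int:
        return self.structures.shape[0]


@dataclass
class FeatureMatrix:
    """Frames-by-features matrix with featurizer provenance.

    ``provenance`` has one (trajectory index, frame index) row per feature
    row; ``traj_lengths`` records how the rows split back into trajectories.
    """

    values: np.ndarray
    featurizer_id: str
    params: dict = field(default_factory=dict)
    provenance: np.ndarray | None = None
    traj_lengths: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def split_by_trajectory(self) -> list[np.ndarray]:
        if self.traj_lengths is None:
            raise ValueError("no trajectory split recorded")
        return np.split(self.values, np.cumsum(self.traj_lengths)[:-1])


def pairwise_rmsd_matrix(frames: np.ndarray) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs between all frame pairs."""
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    D = np.zeros((n, n))
    for i in range(n - 1):
        D[i, i + 1 :] = geometry.rmsd_to_reference(frames[i + 1 :], frames[i])
    return D + D.T


def _kmedoids_pam(D: np.ndarray, k: int, seed: int, max_iter: int = 100) -> np.ndarray:
    """PAM-style k-medoids on a precomputed distance matrix.

    k-means++-style seeding (squared-distance weighting) followed by
    alternating assignment and exhaustive in-cluster medoid search until the
    medoid set is stable.  Returns medoid indices.
    """
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        d2 = np.min(D[:, medoids], axis=1) ** 2
        total = d2.sum()
        if total <= 0:
            remaining = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(remaining[rng.integers(remaining.size)]))
            continue
        medoids.append(int(rng.choice(n, p=d2 / total)))
    medoids = np.array(sorted(medoids))
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                # keep the old medoid; PAM with k <= n distinct points rarely hits this
                continue
            sub = D[np.ix_(members, members)]
            new[c] = members[int(np.argmin(sub.sum(axis=1)))]
        new = np.array(sorted(new))
        if np.array_equal(new, medoids):
            break
        medoids = new
    return medoids


def select_references(
    pool: list[Trajectory],
    k: int,
    seed: int,
    max_pool: int = 2000,
) -> ReferenceSet:
    """Select ``k`` reference structures as k-medoid cluster centers.

    Medoids minimise summed in-cluster RMSD under PAM alternation on the
    pairwise-RMSD matrix.  When the pool holds more than ``max_pool`` frames it
    is strided down to at most ``max_pool`` before the O(pool^2) RMSD matrix is
    built; references are still genuine pool frames.
    """
    coords, prov = concatenate_frames(pool)
    n = coords.shape[0]
    if k > n:
        raise ValueError(f"cannot select {k} references from {n} frames")
    if n > max_pool:
        stride = int(np.ceil(n / max_pool))
        keep = np.arange(0, n, stride)
        coords, prov = coords[keep], prov[keep]
        n = coords.shape[0]
        if k > n:
            raise ValueError("max_pool subsampling left fewer frames than k")
    D = pairwise_rmsd_matrix(coords)
    medoids = _kmedoids_pam(D, k, seed)
    return ReferenceSet(structures=coords[medoids], source_frame_indices=prov[medoids])


def rmsd_kernel_features(
    traj: Trajectory | list[Trajectory],
    refs: ReferenceSet,
    sigma: float = 0.5,
) -> FeatureMatrix:
    """Gaussian RMSD-kernel features: entry (i, j) = exp(-RMSD(i, j)^2 / 2 sigma^2).

    RMSDs are minimum (superposed) RMSDs against each reference structure;
    entries lie in (0, 1], with 1 exactly when a frame coincides with a
    reference up to rigid motion.
    """
    trajs = [traj] if isinstance(traj, Trajectory) else list(traj)
    coords, prov = concatenate_frames(trajs)
    if coords.shape[1] != refs.structures.shape[1]:
        raise ValueError(
            f"bead count mismatch: trajectory has {coords.shape[1]}, "
            f"references have {refs.structures.shape[1]}"
        )
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    F = np.empty((coords.shape[0], refs.k))
    for j in range(refs.k):
        r = geometry.rmsd_to_reference(coords, refs.structures[j])
        F[:, j] = np.exp(-(r**2) / (2.0 * sigma**2))
    return FeatureMatrix(
        values=F,
        featurizer_id="rmsd_kernel",
        params={"sigma": sigma, "reference_count": refs.k},
        provenance=prov,
        traj_lengths=tuple(len(t) for t in trajs),
    )


def calpha_position_features(
    traj: Trajectory | list[Trajectory], ref: np.ndarray
) -> FeatureMatrix:
    """Superposed-coordinate features: each frame aligned onto ``ref``, flattened.

    Rows are bead-major (x, y, z) flattened coordinates after removing the
    optimal rigid transform onto the reference frame — the bead analogue of
    featurizing by C-alpha positions superimposed onto a crystal structure.
    """
    trajs = [traj] if isinstance(traj, Trajectory) else list(traj)
    coords, prov = concatenate_frames(trajs)
    ref = np.asarray(ref, dtype=float)
    if coords.shape[1] != ref.shape[0]:
        raise ValueError("bead count mismatch with reference frame")
    aligned = geometry.superpose_onto(coords, ref)
    return FeatureMatrix(
        values=aligned.reshape(coords.shape[0], -1),
        featurizer_id="superposed_positions",
        params={"n_beads": int(ref.shape[0])},
        provenance=prov,
        traj_lengths=tuple(len(t) for t in trajs),
    )


def pca_reduce(
    F: FeatureMatrix, n_components: int, seed: int = 0
) -> tuple[FeatureMatrix, np.ndarray]:
    """Mean-centered PCA projection onto the top-variance components.

    Uses the full (deterministic) SVD solver, so ``seed`` does not influence
    the result; it is accepted for interface uniformity.  Component signs are
    fixed by forcing each component's largest-magnitude loading positive.
    Raises if ``n_components`` exceeds the feature count or the matrix rank.
    """
    if n_components < 1 or n_components > F.n_features:
        raise ValueError(
            f"n_components={n_components} invalid for {F.n_features} features"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(F.values)
    rank = int(np.sum(pca.explained_variance_ > 1e-12 * max(pca.explained_variance_[0], 1)))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    loadings = pca.components_
    flip = np.sign(loadings[np.arange(n_components), np.argmax(np.abs(loadings), axis=1)])
    loadings = loadings * flip[:, None]
    proj = proj * flip[None, :]
    out = FeatureMatrix(
        values=proj,
        featurizer_id=f"{F.featurizer_id}+pca",
        params={**F.params, "n_components": n_components},
        provenance=F.provenance,
        traj_lengths=F.traj_lengths,
    )
    return out, loadings
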