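"""Adaptive-sampling restarts from cluster centers of the sampled pool.

One round: featurize the pooled trajectories by superposed coordinates,
reduce to ``pca_dims`` principal components (default 15), k-means into
``n_clusters`` microstates (default 2000), draw ``n_restarts`` clusters
uniformly without replacement (default 100), and restart a short simulation
(default the equivalent of 100 ns) from the pool frame nearest each chosen
cluster center — the random-cluster restart strategy, with fresh noise per
restart playing the role of Maxwell-distributed restart velocities in the
overdamped surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cluster as _cluster
from . import featurize as _featurize
from .trajectory import Trajectory, concatenate_frames

__all__ = ["AdaptiveConfig", "RestartFrame", "adaptive_round", "run_adaptive_campaign"]


@dataclass(frozen=True)
class AdaptiveConfig:
    """Parameters of one adaptive round (full-scale defaults: 15/2000/100/100 ns)."""

    pca_dims: int = 15
    n_clusters: int = 2000
    n_restarts: int = 100
    restart_length: int = 1000  # frames; 1000 x 0.1 ns = 100 ns
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pca_dims, self.n_clusters, self.n_restarts, self.restart_length) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_restarts > self.n_clusters:
            raise ValueError("n_restarts cannot exceed n_clusters")

    @classmethod
    def test_scale(cls, seed: int = 0) -> "AdaptiveConfig":
        """Scaled-down defaults for desk-size runs."""
        return cls(pca_dims=5, n_clusters=50, n_restarts=10, restart_length=200, seed=seed)


@dataclass(frozen=True)
class RestartFrame:
    """A restart structure with its provenance into the pool."""

    coords: np.ndarray
    traj_index: int
    frame_index: int
    cluster_id: int


def adaptive_round(pool: list[Trajectory], cfg: AdaptiveConfig) -> list[RestartFrame]:
    """Pick restart structures: PCA + k-means on the pool, random clusters,
    nearest pool frame to each chosen cluster center.

    Restart frames are always genuine members of the pool, never
    interpolations.  Deterministic under a fixed ``cfg.seed``.
    """
    coords, prov = concatenate_frames(pool)
    n = coords.shape[0]
    if n < cfg.n_clusters:
        raise ValueError(
            f"pool has {n} frames, fewer than n_clusters={cfg.n_clusters}"
        )
    ref = pool[0].coords[0]
    feats = _featurize.calpha_position_features(pool, ref)
    dims = min(cfg.pca_dims, feats.n_features)
    reduced, _ = _featurize.pca_reduce(feats, dims)
    disc = _cluster.kmeans(reduced, cfg.n_clusters, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    chosen = rng.choice(cfg.n_clusters, size=cfg.n_restarts, replace=False)
    out = []
    for c in chosen:
        members = np.flatnonzero(disc.labels == c)
        if members.size == 0:  # unreachable after empty-cluster repair
            continue
        d = np.linalg.norm(reduced.values[members] - disc.centers[c], axis=1)
        best = members[int(np.argmin(d))]
        out.append(
            RestartFrame(
                coords=coords[best],
                traj_index=int(prov[best, 0]),
                frame_index=int(prov[best, 1]),
                cluster_id=int(c),
            )
        )
    return out


def run_adaptive_campaign(
    simulator,
    initial: list[Trajectory],
    rounds: int,
    cfg: AdaptiveConfig,
) -> tuple[list[Trajectory], list[dict]]:
    """Alternate simulation restarts and adaptive rounds.

    ``simulator`` must be a callable ``simulator(restart: RestartFrame,
    n_frames: int, seed: int) -> Trajectory`` (the synthetic Langevin engine
    provides one).  Per-round seeds derive from ``cfg.seed`` by a counter:
    round r, restart j uses seed ``cfg.seed + 1000 * (r + 1) + j``.  The pool
    grows monotonically and every generated trajectory records its round,
    parent trajectory/frame and seed.  A simulator failure aborts the round
    but preserves the partial pool.
    """
    pool = list(initial)
    log: list[dict] = []
    for r in range(rounds):
        round_cfg = AdaptiveConfig(
            pca_dims=cfg.pca_dims,
            n_clusters=cfg.n_clusters,
            n_restarts=cfg.n_restarts,
            restart_length=cfg.restart_length,
            seed=cfg.seed + 1000 * (r + 1),
        )
        restarts = adaptive_round(pool, round_cfg)
        for j, rf in enumerate(restarts):
            seed = cfg.seed + 1000 * (r + 1) + j
            try:
                traj = simulator(rf, cfg.restart_length, seed)
            except Exception as exc:  # noqa: BLE001 - partial pool is the contract
                log.append({"round": r, "restart": j, "error": repr(exc)})
                break
            traj.meta.update(
                {
                    "round": r,
                    "parent_traj": rf.traj_index,
                    "parent_frame": rf.frame_index,
                    "cluster_id": rf.cluster_id,
                    "seed": seed,
                }
            )
            pool.append(traj)
            log.append(
                {
                    "round": r,
                    "restart": j,
                    "parent_traj": rf.traj_index,
                    "parent_frame": rf.frame_index,
                    "cluster_id": rf.cluster_id,
                    "seed": seed,
                    "n_frames": len(traj),
                }
            )
    return pool, log
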