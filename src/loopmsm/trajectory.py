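"""Lightweight trajectory container for bead-level loop models.

A :class:`Trajectory` holds an ordered stack of frames of labelled 3-D bead
coordinates, a frame time step, and a per-bead group tag (``"SEL"``, ``"LEL"``,
``"core"``, ...).  Coordinates are in angstroms, times in nanoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trajectory:
    """Ordered frames of labelled 3-D bead coordinates.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_beads, 3)
        Bead coordinates in angstroms.
    groups : sequence of str, length n_beads
        Group tag per bead (e.g. ``"SEL"``, ``"LEL"``).
    dt : float
        Time per frame in nanoseconds (default 0.1 ns, the subsampling stride
        used throughout the pipeline).
    meta : dict
        Free-form provenance (trajectory id, parent frame, seeds, ...).
    """

    coords: np.ndarray
    groups: tuple[str, ...]
    dt: float = 0.1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_beads, 3), got {self.coords.shape}"
            )
        self.groups = tuple(str(g) for g in self.groups)
        if len(self.groups) != self.coords.shape[1]:
            raise ValueError(
                f"{len(self.groups)} group tags for {self.coords.shape[1]} beads"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def group_indices(self, tag: str) -> np.ndarray:
        """Indices of the beads carrying ``tag``; error naming the tag if empty."""
        idx = np.flatnonzero(np.asarray(self.groups) == tag)
        if idx.size == 0:
            raise ValueError(f"group {tag!r} is empty in this trajectory")
        return idx

    def frame(self, i: int) -> np.ndarray:
        """Coordinates of frame ``i`` as an (n_beads, 3) array."""
        return self.coords[i]

    def slice(self, sl: slice | np.ndarray) -> "Trajectory":
        return Trajectory(self.coords[sl], self.groups, self.dt, dict(self.meta))


def concatenate_frames(trajs: list[Trajectory]) -> tuple[np.ndarray, np.ndarray]:
    """Stack all frames of ``trajs`` into one array plus (traj_id, frame_id) provenance.

    Returns ``(coords, provenance)`` where ``coords`` has shape
    (total_frames, n_beads, 3) and ``provenance`` has shape (total_frames, 2)
    with columns (trajectory index in the input list, frame index within it).
    """
    if not trajs:
        raise ValueError("empty trajectory list")
    nb = trajs[0].n_beads
    for t in trajs:
        if t.n_beads != nb:
            raise ValueError("trajectories have inconsistent bead counts")
    coords = np.concatenate([t.coords for t in trajs], axis=0)
    prov = np.concatenate(
        [np.column_stack([np.full(len(t), i), np.arange(len(t))]) for i, t in enumerate(trajs)]
    ).astype(int)
    return coords, prov
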