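"""File formats, run configuration and artifact metadata.

Conventions: coordinates in angstroms, times in nanoseconds, 0-based frame
indexing everywhere.  Trajectories round-trip through XYZ (one model per
frame, the element column reused as the group tag) and multi-model PDB
(MODEL/ENDMDL via biotite, group tag in the chain ID).  Tabular artifacts are
CSV; ground truth and metadata sidecars are JSON; run configuration is TOML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import DiscreteTrajectory, GroundTruth, FRAME_DT_NS
from .trajectory import Trajectory

__all__ = [
    "RunConfig",
    "read_trajectory",
    "write_trajectory",
    "read_xyz",
    "write_xyz",
    "read_pdb",
    "write_pdb",
    "write_dtrajs_csv",
    "read_dtrajs_csv",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_series_csv",
    "write_ground_truth",
    "read_ground_truth",
    "write_sidecar",
    "parse_span_ns",
]

_CHAIN_OF_GROUP = {"SEL": "S", "LEL": "L", "core": "C"}
_GROUP_OF_CHAIN = {v: k for k, v in _CHAIN_OF_GROUP.items()}


# ---------------------------------------------------------------------------
# trajectories


def write_xyz(traj: Trajectory, path) -> None:
    """Multi-model XYZ: element column carries the group tag; %.6f precision."""
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{traj.n_beads}\n")
            fh.write(f"frame {i} dt_ns {traj.dt:.6g}\n")
            for tag, (x, y, z) in zip(traj.groups, traj.coords[i]):
                fh.write(f"{tag} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> Trajectory:
    """Read an XYZ trajectory written by :func:`write_xyz`."""
    frames, groups, dt = [], None, FRAME_DT_NS
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    n_lines = len(lines)
    frame_no = 0
    while ln < n_lines:
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            nb = int(lines[ln].strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{ln + 1}: expected bead count, got {lines[ln]!r}") from exc
        comment = lines[ln + 1].split()
        if "dt_ns" in comment:
            dt = float(comment[comment.index("dt_ns") + 1])
        tags, xyz = [], []
        for j in range(nb):
            parts = lines[ln + 2 + j].split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln + 3 + j}: malformed coordinate line")
            tags.append(parts[0])
            try:
                xyz.append([float(p) for p in parts[1:]])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{ln + 3 + j}: malformed coordinate field"
                ) from exc
        if groups is None:
            groups = tuple(tags)
        elif tuple(tags) != groups or nb != len(groups):
            raise ValueError(f"inconsistent bead count or tags at frame {frame_no}")
        frames.append(xyz)
        ln += 2 + nb
        frame_no += 1
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return Trajectory(np.array(frames), groups, dt=dt)


def write_pdb(traj: Trajectory, path) -> None:
    """Multi-model PDB (MODEL/ENDMDL) through biotite; chain ID = group tag."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = traj.n_beads
    template = struc.AtomArray(n)
    template.coord = traj.coords[0].astype(np.float32)
    template.chain_id = np.array(
        [_CHAIN_OF_GROUP.get(g, g[:1].upper()) for g in traj.groups]
    )
    template.res_id = np.arange(1, n + 1)
    template.res_name = np.array(["GLY"] * n)
    template.atom_name = np.array(["CA"] * n)
    template.element = np.array(["C"] * n)
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = traj.coords.astype(np.float32)
    for annot in ("chain_id", "res_id", "res_name", "atom_name", "element"):
        stack.set_annotation(annot, template.get_annotation(annot))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb(path, dt: float = FRAME_DT_NS) -> Trajectory:
    """Read a multi-model PDB written by :func:`write_pdb` (frame per MODEL)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    groups = tuple(_GROUP_OF_CHAIN.get(c, c) for c in stack.chain_id)
    return Trajectory(coords, groups, dt=dt)


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "xyz":
        write_xyz(traj, path)
    elif fmt == "pdb":
        write_pdb(traj, path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_trajectory(path, fmt: str | None = None) -> Trajectory:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing trajectory file: {path}")
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "xyz":
        return read_xyz(path)
    if fmt == "pdb":
        return read_pdb(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# tabular artifacts


def write_dtrajs_csv(dtrajs: list, path) -> None:
    """Discrete trajectories as long-format CSV (trajectory, step, state)."""
    rows = []
    for i, d in enumerate(dtrajs):
        labels = d.labels if isinstance(d, DiscreteTrajectory) else np.asarray(d, dtype=int)
        rows.append(
            pd.DataFrame(
                {"trajectory": i, "step": np.arange(len(labels)), "state": labels}
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_dtrajs_csv(path, lag_unit: float = FRAME_DT_NS) -> list[DiscreteTrajectory]:
    df = pd.read_csv(path)
    return [
        DiscreteTrajectory(labels=g.sort_values("step")["state"].to_numpy(), lag_unit=lag_unit)
        for _, g in df.groupby("trajectory")
    ]


def write_matrix_csv(M: np.ndarray, path, active_set=None) -> None:
    """Matrix as CSV; the header row carries the active-set state ids."""
    M = np.asarray(M)
    cols = (
        [str(int(s)) for s in active_set]
        if active_set is not None
        else [str(i) for i in range(M.shape[1])]
    )
    pd.DataFrame(M, columns=cols).to_csv(path, index=False, float_format="%.12g")


def read_matrix_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), np.array([int(c) for c in df.columns])


def write_series_csv(times: np.ndarray, values: np.ndarray, path, names=("time_ns", "value")) -> None:
    pd.DataFrame({names[0]: times, names[1]: values}).to_csv(
        path, index=False, float_format="%.10g"
    )


def write_ground_truth(gt: GroundTruth, path) -> None:
    payload = {
        "transition_matrix": gt.transition_matrix.tolist(),
        "timescales_ns": gt.timescales.tolist(),
        "lag_ns": gt.lag_ns,
        "state_of_frame": None if gt.state_of_frame is None else gt.state_of_frame.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        transition_matrix=np.array(payload["transition_matrix"]),
        timescales=np.array(payload["timescales_ns"]),
        state_of_frame=None
        if payload.get("state_of_frame") is None
        else np.array(payload["state_of_frame"]),
        lag_ns=payload.get("lag_ns"),
    )


def write_sidecar(artifact_path, config: "RunConfig", extra: dict | None = None) -> None:
    """JSON metadata sidecar next to an artifact: config hash, seed, versions."""
    import loopmsm

    meta = {
        "config_sha256": config.digest(),
        "seed": config.seed,
        "loopmsm_version": getattr(loopmsm, "__version__", "unknown"),
        "numpy_version": np.__version__,
    }
    if extra:
        meta.update(extra)
    Path(str(artifact_path) + ".meta.json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# configuration


def parse_span_ns(span) -> float:
    """Parse a reconstruction span with an explicit unit suffix (ns/us/ms)."""
    if isinstance(span, (int, float)):
        return float(span)
    s = str(span).strip()
    for suffix, mult in (("ns", 1.0), ("us", 1e3), ("ms", 1e6)):
        if s.endswith(suffix):
            return float(s[: -len(suffix)]) * mult
    raise ValueError(f"span {span!r} needs a unit suffix ns/us/ms")


@dataclass
class SimulationConfig:
    n_trajectories: int = 100
    frames_per_trajectory: int = 1000  # 0.1 ns frames -> 100 ns each
    dt_ns: float = 0.01  # integration step; 10 substeps per frame
    friction: float = 1.0


@dataclass
class FeaturizeConfig:
    sigma: float = 0.5
    reference_count: int = 50
    max_pool: int = 2000


@dataclass
class ClusterConfig:
    n_clusters: int = 500


@dataclass
class MSMConfig:
    lag_ns: float = 20.0
    reversible: bool = True
    folds: int = 3
    m_eigs: int = 5


@dataclass
class AdaptiveSection:
    pca_dims: int = 15
    n_clusters: int = 2000
    n_restarts: int = 100
    restart_frames: int = 1000  # 100 ns at the 0.1 ns stride
    rounds: int = 1


@dataclass
class ContactConfig:
    d0: float = 8.0
    n: int = 6
    m: int = 12


@dataclass
class ReconstructionConfig:
    spans: tuple = ("20us", "100us", "15ms")


@dataclass
class ReportConfig:
    closed_min: float = 0.6
    open_max: float = 0.2
    n_bins: int = 50


@dataclass
class RunConfig:
    """Every stage's parameters, with the pipeline's canonical defaults.

    Full-scale defaults: kernel sigma 0.5 A against 50 references, 500
    microstates, 20 ns lag, 3-fold GMRQ, adaptive round 15 PCA dims / 2000
    clusters / 100 restarts of 100 ns, contact d0 = 8 A with n = 6, m = 12,
    and 20 us / 100 us / 15 ms reconstructions.  ``test_scale()`` returns a
    desk-size variant of the same study design.
    """

    seed: int = 0
    scale: str = "full"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    featurize: FeaturizeConfig = field(default_factory=FeaturizeConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    msm: MSMConfig = field(default_factory=MSMConfig)
    adaptive: AdaptiveSection = field(default_factory=AdaptiveSection)
    contact: ContactConfig = field(default_factory=ContactConfig)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    report: ReportConfig = field(default_factory=ReportConfig)

    @classmethod
    def test_scale(cls, seed: int = 0) -> "RunConfig":
        """Scaled-down configuration preserving the study design."""
        return cls(
            seed=seed,
            scale="test",
            simulation=SimulationConfig(n_trajectories=24, frames_per_trajectory=2500),
            featurize=FeaturizeConfig(reference_count=20, max_pool=1200),
            cluster=ClusterConfig(n_clusters=100),
            adaptive=AdaptiveSection(
                pca_dims=5, n_clusters=50, n_restarts=10, restart_frames=500, rounds=1
            ),
            reconstruction=ReconstructionConfig(spans=("20us", "100us", "1ms")),
        )

    # -- TOML round trip ----------------------------------------------------

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "simulation": SimulationConfig,
            "featurize": FeaturizeConfig,
            "cluster": ClusterConfig,
            "msm": MSMConfig,
            "adaptive": AdaptiveSection,
            "contact": ContactConfig,
            "reconstruction": ReconstructionConfig,
            "report": ReportConfig,
        }
        kwargs: dict = {}
        for key, value in data.items():
            if key in ("seed", "scale"):
                kwargs[key] = value
            elif key in sections:
                klass = sections[key]
                names = {f.name for f in dataclasses.fields(klass)}
                unknown = set(value) - names
                if unknown:
                    raise ValueError(f"unknown keys in [{key}]: {sorted(unknown)}")
                if key == "reconstruction" and "spans" in value:
                    value = {**value, "spans": tuple(value["spans"])}
                kwargs[key] = klass(**value)
            else:
                raise ValueError(f"unknown config section or key: {key}")
        return cls(**kwargs)

    def to_toml_str(self) -> str:
        def fmt(v):
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, (int, float)):
                return repr(v)
            if isinstance(v, str):
                return json.dumps(v)
            if isinstance(v, (list, tuple)):
                return "[" + ", ".join(fmt(x) for x in v) + "]"
            raise TypeError(f"cannot serialise {v!r}")

        lines = [f"seed = {fmt(self.seed)}", f"scale = {fmt(self.scale)}"]
        for name in (
            "simulation", "featurize", "cluster", "msm",
            "adaptive", "contact", "reconstruction", "report",
        ):
            section = getattr(self, name)
            lines.append(f"\n[{name}]")
            for f in dataclasses.fields(section):
                lines.append(f"{f.name} = {fmt(getattr(section, f.name))}")
        return "\n".join(lines) + "\n"

    def to_toml(self, path) -> None:
        Path(path).write_text(self.to_toml_str())

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()

    @property
    def lag_frames(self) -> int:
        return int(round(self.msm.lag_ns / FRAME_DT_NS))

    def span_steps(self, span) -> int:
        return int(round(parse_span_ns(span) / self.msm.lag_ns))
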