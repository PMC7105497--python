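"""End-to-end orchestration: simulate, featurize, discretize, MSM, report.

``run_pipeline`` executes the full chain of the analysis on the synthetic
surrogate under a :class:`~loopmsm.io.RunConfig`: generate many short gap
trajectories (plus adaptive-sampling rounds), featurize them with the RMSD
kernel against k-medoid references, discretize with k-means, estimate the
MSM at the 20 ns lag, reconstruct long pseudo-trajectories and extract the
SEL-LEL contact observable.

Stage seeds derive from the master seed by a fixed counter scheme:
simulation ``seed``, frame embedding ``seed + 100 + i``, reference selection
``seed + 500``, k-means ``seed + 600``, reconstructions ``seed + 700 + j``,
adaptive campaign ``seed + 800``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import adaptive as _adaptive
from . import cluster as _cluster
from . import featurize as _featurize
from . import msm as _msm
from . import report as _report
from .geometry import ContactParams
from .io import RunConfig, parse_span_ns
from .synthetic import (
    FRAME_DT_NS,
    LoopModelSpec,
    PotentialSpec,
    default_surrogate,
    embed_loop_frames,
    simulate_langevin_gap_batch,
)
from .trajectory import Trajectory

__all__ = [
    "SurrogateSimulator",
    "KernelDiscretizationPipeline",
    "PipelineResult",
    "generate_pool",
    "analyze_pool",
    "gmrq_for_config",
    "run_pipeline",
]


class SurrogateSimulator:
    """Langevin engine over the gap coordinate plus the loop embedding.

    Serves both as the initial-pool generator and as the restart simulator
    handle for the adaptive campaign (restart gaps are read off the restart
    frame by projecting the LEL-SEL centroid offset onto the gap axis).
    """

    def __init__(
        self,
        potential: PotentialSpec,
        loops: LoopModelSpec,
        dt_ns: float = 0.01,
        friction: float = 1.0,
        frame_dt: float = FRAME_DT_NS,
    ) -> None:
        self.potential = potential
        self.loops = loops
        self.dt_ns = dt_ns
        self.friction = friction
        self.frame_dt = frame_dt
        self.substeps = int(round(frame_dt / dt_ns))
        if abs(self.substeps * dt_ns - frame_dt) > 1e-9:
            raise ValueError("dt_ns must divide the 0.1 ns frame stride")
        sel_c = self.loops.sel_template.mean(axis=0)
        lel_c = self.loops.lel_template.mean(axis=0)
        self._baseline = float(np.dot(self.loops.gap_axis, lel_c - sel_c))

    def gap_of_frame(self, coords: np.ndarray) -> float:
        """Estimate the gap of a bead frame from the loop centroid offset."""
        groups = np.asarray(self.loops.groups)
        sel = coords[groups == "SEL"].mean(axis=0)
        lel = coords[groups == "LEL"].mean(axis=0)
        return float(np.dot(self.loops.gap_axis, lel - sel) - self._baseline)

    def initial_pool(self, n_trajectories: int, n_frames: int, seed: int) -> list[Trajectory]:
        """Batch of independent trajectories all started in the closed well."""
        x0 = np.full(n_trajectories, self.potential.centers[0])
        gaps = simulate_langevin_gap_batch(
            self.potential,
            n_steps=n_frames * self.substeps,
            dt=self.dt_ns,
            friction=self.friction,
            seed=seed,
            x0=x0,
            record_stride=self.substeps,
        )
        pool = []
        for i in range(n_trajectories):
            traj = embed_loop_frames(gaps[:, i], self.loops, seed=seed + 100 + i)
            traj.meta.update({"id": f"init-{i}", "round": -1, "seed": seed})
            traj.meta["gaps"] = gaps[:, i]
            pool.append(traj)
        return pool

    def __call__(self, restart: "_adaptive.RestartFrame", n_frames: int, seed: int) -> Trajectory:
        g0 = self.gap_of_frame(restart.coords)
        gaps = simulate_langevin_gap_batch(
            self.potential,
            n_steps=n_frames * self.substeps,
            dt=self.dt_ns,
            friction=self.friction,
            seed=seed,
            x0=np.array([g0]),
            record_stride=self.substeps,
        )[:, 0]
        traj = embed_loop_frames(gaps, self.loops, seed=seed)
        traj.meta["gaps"] = gaps
        return traj


class KernelDiscretizationPipeline:
    """Featurize-and-discretize pipeline for GMRQ cross-validation.

    fit: select k-medoid references and k-means centers from the training
    trajectories only; transform: kernel-featurize against those references
    and assign to those centers.
    """

    def __init__(
        self,
        sigma: float = 0.5,
        n_references: int = 50,
        n_clusters: int = 500,
        seed: int = 0,
        max_pool: int = 2000,
    ) -> None:
        self.sigma = sigma
        self.n_references = n_references
        self.n_clusters = n_clusters
        self.seed = seed
        self.max_pool = max_pool
        self.refs = None
        self.centers = None

    @property
    def params(self) -> dict:
        return {
            "sigma": self.sigma,
            "n_references": self.n_references,
            "n_clusters": self.n_clusters,
            "seed": self.seed,
        }

    def fit(self, trajs: list[Trajectory]) -> "KernelDiscretizationPipeline":
        self.refs = _featurize.select_references(
            trajs, self.n_references, seed=self.seed + 1, max_pool=self.max_pool
        )
        F = _featurize.rmsd_kernel_features(trajs, self.refs, self.sigma)
        disc = _cluster.kmeans(F, self.n_clusters, seed=self.seed + 2)
        self.centers = disc.centers
        return self

    def transform(self, trajs: list[Trajectory]) -> list[np.ndarray]:
        if self.refs is None:
            raise RuntimeError("pipeline not fitted")
        out = []
        for t in trajs:
            F = _featurize.rmsd_kernel_features(t, self.refs, self.sigma)
            out.append(_cluster.assign(F, self.centers))
        return out


@dataclass
class PipelineResult:
    """Everything the full chain produces, in memory."""

    config: RunConfig
    pool: list[Trajectory]
    refs: "_featurize.ReferenceSet"
    features: "_featurize.FeatureMatrix"
    discretization: "_cluster.Discretization"
    msm: "_msm.MSMResults"
    frame_index: dict
    pool_contacts: np.ndarray
    reconstructions: dict = field(default_factory=dict)
    contact_series: dict = field(default_factory=dict)
    state_fractions: dict = field(default_factory=dict)
    campaign_log: list = field(default_factory=list)


def generate_pool(config: RunConfig) -> tuple[list[Trajectory], list[dict], SurrogateSimulator]:
    """Initial short trajectories plus the configured adaptive rounds."""
    potential, loops, _ = default_surrogate()
    sim = SurrogateSimulator(
        potential, loops, dt_ns=config.simulation.dt_ns, friction=config.simulation.friction
    )
    pool = sim.initial_pool(
        config.simulation.n_trajectories,
        config.simulation.frames_per_trajectory,
        seed=config.seed,
    )
    log: list[dict] = []
    if config.adaptive.rounds > 0:
        cfg = _adaptive.AdaptiveConfig(
            pca_dims=config.adaptive.pca_dims,
            n_clusters=config.adaptive.n_clusters,
            n_restarts=config.adaptive.n_restarts,
            restart_length=config.adaptive.restart_frames,
            seed=config.seed + 800,
        )
        pool, log = _adaptive.run_adaptive_campaign(sim, pool, config.adaptive.rounds, cfg)
    return pool, log, sim


def _pool_contact_values(pool: list[Trajectory], params: ContactParams) -> tuple[np.ndarray, np.ndarray]:
    """Contact value of every pool frame, plus flat offsets per trajectory."""
    from .geometry import contact, min_group_distance_series

    values = []
    for t in pool:
        d = min_group_distance_series(t.coords, t.groups, "SEL", "LEL")
        values.append(np.atleast_1d(contact(d, params)))
    offsets = np.concatenate([[0], np.cumsum([len(t) for t in pool])])[:-1]
    return np.concatenate(values), offsets


def analyze_pool(pool: list[Trajectory], config: RunConfig, campaign_log=None) -> PipelineResult:
    """Featurize, discretize, estimate the MSM, reconstruct and report."""
    fz = config.featurize
    refs = _featurize.select_references(
        pool, fz.reference_count, seed=config.seed + 500, max_pool=fz.max_pool
    )
    F = _featurize.rmsd_kernel_features(pool, refs, fz.sigma)
    disc = _cluster.kmeans(F, config.cluster.n_clusters, seed=config.seed + 600)
    model = _msm.MarkovStateModel(
        disc.split_labels(),
        lag=config.lag_frames,
        dt=FRAME_DT_NS,
        reversible=config.msm.reversible,
    )
    results = model.fit()
    frame_index = _msm.frames_by_state(disc.labels, F.provenance)
    cparams = ContactParams(config.contact.d0, config.contact.n, config.contact.m)
    pool_contacts, offsets = _pool_contact_values(pool, cparams)
    out = PipelineResult(
        config=config,
        pool=pool,
        refs=refs,
        features=F,
        discretization=disc,
        msm=results,
        frame_index=frame_index,
        pool_contacts=pool_contacts,
        campaign_log=campaign_log or [],
    )
    thr = _report.StateThresholds(config.report.closed_min, config.report.open_max)
    for j, span in enumerate(config.reconstruction.spans):
        n_steps = config.span_steps(span)
        rec = results.synthesize(frame_index, n_steps, seed=config.seed + 700 + j)
        flat = offsets[rec.frame_refs[:, 0]] + rec.frame_refs[:, 1]
        series = _report.ContactSeries(
            times=np.arange(n_steps) * rec.lag_ns,  # step index * lag
            values=pool_contacts[flat],
            params=cparams,
            source=str(span),
        )
        out.reconstructions[str(span)] = rec
        out.contact_series[str(span)] = series
        out.state_fractions[str(span)] = _report.state_fractions(series, thr)
    return out


def gmrq_for_config(pool: list[Trajectory], config: RunConfig) -> "_msm.GMRQResult":
    """3-fold (by default) GMRQ cross-validation of the configured pipeline."""
    pipe = KernelDiscretizationPipeline(
        sigma=config.featurize.sigma,
        n_references=config.featurize.reference_count,
        n_clusters=config.cluster.n_clusters,
        seed=config.seed + 900,
        max_pool=config.featurize.max_pool,
    )
    return _msm.gmrq_cross_validate(
        pool,
        pipe,
        lag=config.lag_frames,
        n_folds=config.msm.folds,
        m_eigs=config.msm.m_eigs,
        seed=config.seed + 901,
    )


def run_pipeline(config: RunConfig, outdir, with_gmrq: bool = False, write_pool: bool = False) -> PipelineResult:
    """Run the full chain and write the artifacts (CSV + JSON sidecars) to ``outdir``."""
    import json
    from pathlib import Path

    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pool, log, _sim = generate_pool(config)
    res = analyze_pool(pool, config, campaign_log=log)

    config.to_toml(outdir / "config.toml")
    if write_pool:
        pooldir = outdir / "pool"
        pooldir.mkdir(exist_ok=True)
        for i, t in enumerate(pool):
            _io.write_xyz(t, pooldir / f"traj-{i:04d}.xyz")
    _io.write_dtrajs_csv(res.discretization.split_labels(), outdir / "dtrajs.csv")
    _io.write_matrix_csv(res.discretization.centers, outdir / "centers.csv")
    _io.write_matrix_csv(
        res.msm.transition_matrix, outdir / "transition_matrix.csv", res.msm.active_set
    )
    _io.write_matrix_csv(
        res.msm.stationary_distribution[None, :], outdir / "stationary.csv", res.msm.active_set
    )
    (outdir / "msm_summary.txt").write_text(res.msm.summary() + "\n")
    for span, series in res.contact_series.items():
        _io.write_series_csv(series.times, series.values, outdir / f"contact_{span}.csv")
    longest = max(res.contact_series, key=lambda s: parse_span_ns(s))
    edges, dens = _report.contact_distribution(
        res.contact_series[longest], config.report.n_bins
    )
    _io.write_series_csv(edges[:-1], dens, outdir / "contact_distribution.csv",
                         names=("bin_left", "density"))
    header = {
        "thresholds": {"closed_min": config.report.closed_min, "open_max": config.report.open_max},
        "state_fractions": res.state_fractions,
        "n_metastable": res.msm.n_metastable(),
        "timescales_ns": [float(t) for t in res.msm.timescales(4)],
    }
    (outdir / "report.json").write_text(json.dumps(header, indent=1))
    if log:
        with open(outdir / "campaign_log.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    if with_gmrq:
        g = gmrq_for_config(pool, config)
        (outdir / "gmrq.json").write_text(
            json.dumps(
                {
                    "train_scores": g.train_scores.tolist(),
                    "test_scores": g.test_scores.tolist(),
                    "fold_valid": g.fold_valid.tolist(),
                    "mean_test_score": g.mean_test_score,
                    "m_eigs": g.m_eigs,
                    "params": g.params,
                },
                indent=1,
            )
        )
    _report.plot_contact_timecourse(
        res.contact_series[longest], str(outdir / "contact_timecourse.png")
    )
    _report.plot_contact_distribution(
        res.contact_series[longest], str(outdir / "contact_distribution.png"),
        config.report.n_bins,
    )
    for name in (
        "dtrajs.csv", "centers.csv", "transition_matrix.csv", "stationary.csv",
        "contact_distribution.csv", "report.json",
    ):
        _io.write_sidecar(outdir / name, config)
    return res
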