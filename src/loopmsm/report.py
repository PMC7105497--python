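"""Contact observables and figure-style outputs.

The SEL-LEL contact is the rational switching function of the minimum
inter-loop distance, evaluated per frame along a (reconstructed) trajectory.
Outputs mirror the usual presentation: the contact time course along a
reconstructed trajectory, its distribution over a longer reconstruction, and
a named-state classification (closed / semi-open / open) by contact
thresholds.  The thresholds are this package's operationalisation — the
conformations are defined structurally (LEL up, apart from the SEL), so the
numeric boundaries are stated in every report header rather than presented as
established values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ContactParams, contact, min_group_distance_series
from .trajectory import Trajectory

__all__ = [
    "ContactSeries",
    "StateThresholds",
    "contact_timecourse",
    "contact_distribution",
    "classify_states",
    "state_fractions",
    "plot_contact_timecourse",
    "plot_contact_distribution",
]


@dataclass
class ContactSeries:
    """Per-frame contact values in (0, 1] with their time axis (ns)."""

    times: np.ndarray
    values: np.ndarray
    params: ContactParams
    source: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0) or np.any(self.values > 1):
            raise ValueError("contact values must lie in (0, 1]")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class StateThresholds:
    """Contact thresholds separating closed / semi-open / open.

    closed: value >= closed_min; open: value <= open_max; semi-open between.
    Defaults (0.6 / 0.2) are package choices, printed in report headers.
    """

    closed_min: float = 0.6
    open_max: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.open_max < self.closed_min < 1.0):
            raise ValueError("need 0 < open_max < closed_min < 1")


def contact_timecourse(
    traj: Trajectory,
    group_a: str = "SEL",
    group_b: str = "LEL",
    params: ContactParams = ContactParams(),
) -> ContactSeries:
    """Contact(min inter-group distance) per frame; time axis = frame index * dt."""
    d = min_group_distance_series(traj.coords, traj.groups, group_a, group_b)
    values = np.atleast_1d(contact(d, params))
    times = np.arange(traj.n_frames) * traj.dt
    return ContactSeries(times=times, values=values, params=params,
                         source=str(traj.meta.get("id", "")))


def contact_distribution(series: ContactSeries, n_bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Density-normalised histogram of the contact values on [0, 1].

    Returns (bin_edges, densities) with sum(density * width) = 1.
    """
    if len(series) == 0:
        raise ValueError("empty contact series")
    densities, edges = np.histogram(series.values, bins=n_bins, range=(0.0, 1.0), density=True)
    return edges, densities


def classify_states(series: ContactSeries, thr: StateThresholds = StateThresholds()) -> np.ndarray:
    """Label every value closed / semi-open / open; boundaries go to the extremes."""
    v = series.values
    out = np.full(v.shape, "semi-open", dtype=object)
    out[v >= thr.closed_min] = "closed"
    out[v <= thr.open_max] = "open"
    return out.astype(str)


def state_fractions(series: ContactSeries, thr: StateThresholds = StateThresholds()) -> dict[str, float]:
    """Fraction of frames in each named state."""
    labels = classify_states(series, thr)
    n = labels.size
    return {s: float(np.sum(labels == s)) / n for s in ("closed", "semi-open", "open")}


def _time_axis_label(times: np.ndarray) -> tuple[np.ndarray, str]:
    span = times[-1]
    if span >= 1e6:
        return times / 1e6, "time [ms]"
    if span >= 1e3:
        return times / 1e3, "time [us]"
    return times, "time [ns]"


def plot_contact_timecourse(series: ContactSeries, path: str) -> None:
    """Courtesy plot of the contact time course; the CSV is the tested artifact."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t, label = _time_axis_label(series.times)
    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.plot(t, series.values, lw=0.4, color="tab:blue")
    ax.set_xlabel(label)
    ax.set_ylabel("SEL-LEL contact")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_contact_distribution(series: ContactSeries, path: str, n_bins: int = 50) -> None:
    """Courtesy plot of the contact distribution; the CSV is the tested artifact."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges, dens = contact_distribution(series, n_bins)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.stairs(dens, edges, fill=True, color="tab:blue", alpha=0.7)
    ax.set_xlabel("SEL-LEL contact")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
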