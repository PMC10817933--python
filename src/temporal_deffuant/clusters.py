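"""Opinion-cluster detection and size/position profiles.

Final opinions are grouped by the epsilon-gap rule: opinions are sorted and
a new cluster opens wherever two successive values differ by at least
``epsilon`` (default 1e-4).  A group only counts as an opinion cluster if it
holds at least a fraction ``min_frac`` (default 1%) of the population;
smaller groups — typically poorly connected individuals stuck between
clusters — are reported as unclustered.

For profiles, each kept cluster contributes its relative size
Omega = S / N at offset dx = position - 0.5 from the centre of the opinion
space; profiles from many runs are aggregated by binning dx.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusterSummary",
    "detect_clusters",
    "filter_major_clusters",
    "summarize_opinions",
    "cluster_profile",
    "aggregate_profiles",
]

EPSILON = 1e-4
MIN_FRAC = 0.01


@dataclass
class ClusterSummary:
    """Detected opinion clusters of one final state."""

    n_nodes: int
    n_clusters: int                      # N_f, clusters holding >= min_frac of N
    sizes: list[int]                     # S_f per kept cluster
    positions: list[float]               # mean opinion of members
    unclustered: int                     # nodes in groups below the size cut
    members: list[list[int]] = field(default_factory=list, repr=False)

    @property
    def omegas(self) -> list[float]:
        """Relative sizes Omega = S_f / N."""
        return [s / self.n_nodes for s in self.sizes]

    @property
    def offsets(self) -> list[float]:
        """Offsets dx = position - 0.5 from the central opinion."""
        return [p - 0.5 for p in self.positions]


def detect_clusters(opinions, epsilon: float = EPSILON) -> list[list[int]]:
    """Partition node indices by the sorted-gap rule.

    Opinions are sorted ascending; a consecutive gap >= epsilon opens a new
    cluster.  Returns the member indices (into the input) of each cluster,
    ordered by opinion.  Independent of input order.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    x = np.asarray(opinions, dtype=float)
    if x.size == 0:
        raise ValueError("opinions must be non-empty")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    # new cluster wherever the consecutive gap reaches epsilon
    breaks = np.nonzero(np.diff(xs) >= epsilon)[0] + 1
    return [grp.tolist() for grp in np.split(order, breaks)]


def filter_major_clusters(
    partition: list[list[int]],
    opinions,
    n_nodes: int | None = None,
    min_frac: float = MIN_FRAC,
) -> ClusterSummary:
    """Apply the minimum-size rule and summarise the kept clusters.

    A cluster is kept if its size is at least ``ceil(min_frac * n_nodes)``
    (inclusive reading of "at least 1% of the population").
    """
    if not 0 < min_frac < 1:
        raise ValueError("min_frac must be in (0, 1)")
    x = np.asarray(opinions, dtype=float)
    if n_nodes is None:
        n_nodes = int(x.size)
    cut = math.ceil(min_frac * n_nodes)
    kept = [c for c in partition if len(c) >= cut]
    sizes = [len(c) for c in kept]
    positions = [float(x[c].mean()) for c in kept]
    total = sum(len(c) for c in partition)
    return ClusterSummary(
        n_nodes=n_nodes,
        n_clusters=len(kept),
        sizes=sizes,
        positions=positions,
        unclustered=total - sum(sizes),
        members=kept,
    )


def summarize_opinions(
    opinions,
    epsilon: float = EPSILON,
    min_frac: float = MIN_FRAC,
) -> ClusterSummary:
    """Detect and filter clusters of a final opinion vector in one call."""
    part = detect_clusters(opinions, epsilon)
    return filter_major_clusters(part, opinions, min_frac=min_frac)


def cluster_profile(summary: ClusterSummary) -> pd.DataFrame:
    """One row per kept cluster: offset dx and relative size Omega."""
    return pd.DataFrame(
        {
            "delta_x": summary.offsets,
            "omega": summary.omegas,
            "size": summary.sizes,
            "position": summary.positions,
        }
    )


def aggregate_profiles(
    profiles: list[pd.DataFrame], bin_width: float = 0.05
) -> pd.DataFrame:
    """Bin cluster offsets across runs and average Omega within bins.

    Bins are centred on multiples of ``bin_width`` covering [-0.5, 0.5].
    Returns columns ``delta_x`` (bin centre), ``omega_mean``, ``omega_se``
    and ``count``.
    """
    if not profiles:
        return pd.DataFrame(columns=["delta_x", "omega_mean", "omega_se", "count"])
    df = pd.concat(profiles, ignore_index=True)
    if df.empty:
        return pd.DataFrame(columns=["delta_x", "omega_mean", "omega_se", "count"])
    centre = np.round(df["delta_x"] / bin_width) * bin_width
    grouped = df.groupby(np.round(centre, 10))["omega"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    out.columns = ["delta_x", "omega_mean", "omega_sd", "count"]
    out["omega_se"] = out["omega_sd"] / np.sqrt(out["count"])
    return out[["delta_x", "omega_mean", "omega_se", "count"]]
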