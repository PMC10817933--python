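"""Replicate design and parameter sweeps.

The canonical experiment crosses network substrates, activation patterns
and the confidence level d.  For each cell of the design, ``n_networks``
independent substrates are generated and each is simulated
``n_runs_per_network`` times with fresh opinion and activation seeds
(defaults 15 x 20 = 300 replicates).  Every lognormal activation pattern
is compared against an exponential process matched to the same mean
inter-event time (the effective, truncation-aware mean).

Seeds are derived from the master seed by stable spawn keys
(cell, network, run), so any single replicate can be reproduced in
isolation and execution order is irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from . import networks as nets
from .activation import InterEventModel, build_schedule, make_interevent_model
from .clusters import summarize_opinions
from .engine import SimulationConfig, init_opinions, run_static_baseline, run_temporal
from .networks import StaticNetwork

__all__ = [
    "NetworkSpec",
    "ActivationSpec",
    "SweepConfig",
    "run_replicate",
    "run_sweep",
    "aggregate",
]

#: default confidence-level grid
D_GRID = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class NetworkSpec:
    """How to generate one substrate."""

    model: str = "er"             # er | ws | fitness
    n_nodes: int = 1000
    mean_degree: float = 20.0     # er
    k_nn: int = 6                 # ws
    rewire_prob: float = 0.33     # ws
    links_per_node: int = 3       # fitness
    beta: float = 0.0             # fitness
    configuration_rewire: bool = False  # degree-preserving null of the above

    def label(self) -> str:
        if self.model == "er":
            base = f"er(k={self.mean_degree:g})"
        elif self.model == "ws":
            base = f"ws(k={self.k_nn},q={self.rewire_prob:g})"
        else:
            base = f"fitness(m={self.links_per_node},beta={self.beta:g})"
        return base + ("+config" if self.configuration_rewire else "")

    def generate(self, seed) -> StaticNetwork:
        rng = default_rng(seed)
        if self.model == "er":
            net = nets.generate_er(self.n_nodes, self.mean_degree, rng)
        elif self.model == "ws":
            net = nets.generate_ws(self.n_nodes, self.k_nn, self.rewire_prob, rng)
        elif self.model == "fitness":
            net = nets.generate_fitness(
                self.n_nodes, self.links_per_node, self.beta, rng
            )
        else:
            raise ValueError(f"unknown network model {self.model!r}")
        if self.configuration_rewire:
            net = nets.rewire_to_configuration(net, seed=rng)
        return net


@dataclass(frozen=True)
class ActivationSpec:
    """How link clocks tick.

    ``family`` "exponential" uses ``rate`` directly; "lognormal" uses
    (nu, sigma) truncated at dt_max.  ``family`` "exponential-matched"
    is the homogeneous comparator of a lognormal pattern: an exponential
    process with the same (effective) mean inter-event time.
    """

    family: str = "exponential"
    rate: float = 1.0
    nu: float = 0.0
    sigma: float = 1.0
    dt_max: Optional[float] = 1.0e6

    def label(self) -> str:
        if self.family == "exponential":
            return f"exp(b={self.rate:g})"
        if self.family == "exponential-matched":
            return f"exp-matched(sigma={self.sigma:g})"
        return f"lognormal(sigma={self.sigma:g})"

    def model(self) -> InterEventModel:
        if self.family == "exponential":
            return make_interevent_model("exponential", rate=self.rate)
        lognorm = make_interevent_model(
            "lognormal", nu=self.nu, sigma=self.sigma, dt_max=self.dt_max
        )
        if self.family == "exponential-matched":
            return make_interevent_model("exponential", rate=1.0 / lognorm.effective_mean)
        if self.family == "lognormal":
            return lognorm
        raise ValueError(f"unknown activation family {self.family!r}")


@dataclass
class SweepConfig:
    """Full factorial sweep definition."""

    networks: tuple[NetworkSpec, ...] = (NetworkSpec(),)
    activations: tuple[ActivationSpec, ...] = (
        ActivationSpec("exponential"),
        ActivationSpec("lognormal", sigma=0.1),
        ActivationSpec("lognormal", sigma=1.0),
        ActivationSpec("lognormal", sigma=2.7),
        ActivationSpec("lognormal", sigma=20.0),
    )
    d_grid: tuple[float, ...] = D_GRID
    mu: float = 0.5
    n_networks: int = 15
    n_runs_per_network: int = 20
    seed: int = 0
    burn_in_per_link: int = 10
    max_events: int = 100_000_000

    @property
    def n_replicates(self) -> int:
        return self.n_networks * self.n_runs_per_network


def _network_seed(master: int, net_spec_idx: int, net_idx: int) -> SeedSequence:
    return SeedSequence(master, spawn_key=(0, net_spec_idx, net_idx))


def _run_seed(master: int, cell_idx: int, net_idx: int, run_idx: int) -> SeedSequence:
    return SeedSequence(master, spawn_key=(1, cell_idx, net_idx, run_idx))


def run_replicate(
    network: StaticNetwork,
    activation: ActivationSpec | None,
    d: float,
    mu: float = 0.5,
    seed=0,
    burn_in_per_link: int = 10,
    max_events: int = 100_000_000,
    stop_time_window: Optional[float] = None,
) -> dict:
    """One simulation replicate -> flat record with cluster summary.

    ``activation`` None runs the static-network baseline (one random edge
    per discrete step) instead of a temporal schedule.  The stopping rule
    is a window of N (= number of nodes) consecutive activations without a
    successful exchange; ``stop_time_window`` optionally adds a window in
    continuous time.
    """
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    s_op, s_act = ss.spawn(2)
    config = SimulationConfig(
        d=d,
        mu=mu,
        stop_window=network.n_nodes,
        stop_time_window=stop_time_window,
        max_events=max_events,
    )
    state = init_opinions(network.n_nodes, default_rng(s_op))
    if activation is None:
        result = run_static_baseline(network, config, state=state)
    else:
        model = activation.model()
        schedule = build_schedule(network, model, s_act)
        exhausted = False
        try:
            schedule.burn(burn_in_per_link * network.n_edges)
        except Exception:
            exhausted = True
        if exhausted:
            result = None
        else:
            result = run_temporal(network, schedule, config, state=state)
    if result is None:
        return {
            "n_f": math.nan,
            "t_f": math.nan,
            "events_to_stable": 0,
            "total_events": 0,
            "unclustered": network.n_nodes,
            "max_omega": math.nan,
            "termination": "exhausted_in_burn_in",
        }
    summary = summarize_opinions(result.final_opinions)
    return {
        "n_f": summary.n_clusters,
        "t_f": result.t_f,
        "events_to_stable": result.events_to_stable,
        "total_events": result.total_events,
        "successful_exchanges": result.successful_exchanges,
        "unclustered": summary.unclustered,
        "max_omega": max(summary.omegas, default=0.0),
        "positions": summary.positions,
        "sizes": summary.sizes,
        "termination": result.termination_reason,
    }


def run_sweep(
    config: SweepConfig,
    checkpoint_dir: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the full factorial design; returns replicate-level records.

    With ``checkpoint_dir``, each cell's records are written to a CSV as
    soon as the cell finishes, and previously checkpointed cells are
    loaded instead of re-run.
    """
    ckpt = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)
    records: list[pd.DataFrame] = []
    cell_idx = -1
    for ni, net_spec in enumerate(config.networks):
        substrates = [
            net_spec.generate(_network_seed(config.seed, ni, j))
            for j in range(config.n_networks)
        ]
        for act_spec in config.activations:
            for d in config.d_grid:
                cell_idx += 1
                cell_name = f"cell{cell_idx:04d}"
                if ckpt and (ckpt / f"{cell_name}.csv").exists():
                    records.append(pd.read_csv(ckpt / f"{cell_name}.csv"))
                    continue
                rows = []
                for j, net in enumerate(substrates):
                    for r in range(config.n_runs_per_network):
                        rec = run_replicate(
                            net,
                            act_spec,
                            d,
                            mu=config.mu,
                            seed=_run_seed(config.seed, cell_idx, j, r),
                            burn_in_per_link=config.burn_in_per_link,
                            max_events=config.max_events,
                        )
                        rec.pop("positions", None)
                        rec.pop("sizes", None)
                        rows.append(
                            {
                                "network": net_spec.label(),
                                "activation": act_spec.label(),
                                "d": d,
                                "net_idx": j,
                                "run_idx": r,
                                **rec,
                            }
                        )
                cell = pd.DataFrame(rows)
                if ckpt:
                    cell.to_csv(ckpt / f"{cell_name}.csv", index=False)
                if progress:
                    print(
                        f"{cell_name}: {net_spec.label()} {act_spec.label()} "
                        f"d={d:g}  <N_f>={cell['n_f'].mean():.2f}",
                        flush=True,
                    )
                records.append(cell)
    return pd.concat(records, ignore_index=True)


def aggregate(raw: pd.DataFrame, value_cols: tuple[str, ...] = ("n_f", "t_f")) -> pd.DataFrame:
    """Tidy per-cell means with standard errors (SE = sd / sqrt(m)).

    SE is NaN for single-replicate cells.
    """
    if raw.empty:
        raise ValueError("no replicate records to aggregate")
    keys = ["network", "activation", "d"]
    out = []
    for key, grp in raw.groupby(keys, sort=False):
        row = dict(zip(keys, key))
        row["n"] = len(grp)
        for col in value_cols:
            vals = grp[col].astype(float)
            row[f"{col}_mean"] = vals.mean()
            sd = vals.std(ddof=1) if len(vals) > 1 else math.nan
            row[f"{col}_se"] = sd / math.sqrt(len(vals)) if len(vals) > 1 else math.nan
        out.append(row)
    return pd.DataFrame(out)
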