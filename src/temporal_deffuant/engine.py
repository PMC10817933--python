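"""The bounded-confidence (Deffuant) opinion update driven by link activations.

Every node i holds an opinion x_i in [0, 1].  When a link (i, j) activates
at time t the pair attempts an exchange: if the opinions differ by less
than the confidence level d (strict inequality),

    x_i <- x_i + mu (x_j - x_i)
    x_j <- x_j + mu (x_i - x_j)        (pre-update values on both lines),

otherwise nothing happens.  mu in [0, 1] is the influence parameter; at the
canonical mu = 0.5 both individuals jump to their midpoint.  Updates
conserve x_i + x_j and contract |x_i - x_j| by exactly |1 - 2 mu|.

An exchange only counts as *successful* for the stopping rule if it changes
the opinions by more than a small numerical tolerance (``quiescence_atol``,
default 1e-6 — two decades below the cluster resolution 1e-4): once every
interacting pair is either closer than the tolerance (local consensus) or
farther apart than d (frozen disagreement), the dynamics is stationary.
The run stops when a window of ``stop_window`` consecutive activations
(and/or ``stop_time_window`` time units) passes without a successful
exchange; the stabilisation time T_f is the time of the last successful
exchange.

``run_static_baseline`` implements the classical static-network Deffuant
model (one uniformly random edge per discrete step), to which the temporal
model with exponential inter-event times is statistically equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from .activation import ActivationSchedule
from .networks import StaticNetwork

__all__ = [
    "OpinionState",
    "SimulationConfig",
    "SimulationResult",
    "init_opinions",
    "attempt_exchange",
    "run_temporal",
    "run_static_baseline",
]

QUIESCENCE_ATOL = 1e-6


@dataclass
class OpinionState:
    """Per-node opinions plus exchange bookkeeping."""

    opinions: np.ndarray
    total_events: int = 0
    successful_exchanges: int = 0
    last_success_event: int = 0

    @property
    def n_nodes(self) -> int:
        return len(self.opinions)


@dataclass
class SimulationConfig:
    """Parameters of one simulation run.

    ``stop_window`` counts consecutive activations without a successful
    exchange (default: the number of nodes N).  ``stop_time_window``, if
    set, additionally stops the run once that much continuous time passes
    without a successful exchange.  ``max_events`` is a hard cap reported
    as a distinct termination reason.
    """

    d: float
    mu: float = 0.5
    stop_window: Optional[int] = None
    stop_time_window: Optional[float] = None
    max_events: int = 100_000_000
    quiescence_atol: float = QUIESCENCE_ATOL
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.d <= 1:
            raise ValueError("confidence level d must be in (0, 1]")
        if not 0 <= self.mu <= 1:
            raise ValueError("influence mu must be in [0, 1]")
        if self.stop_window is not None and self.stop_window < 1:
            raise ValueError("stop_window must be >= 1")


@dataclass
class SimulationResult:
    """Outcome of a run."""

    final_opinions: np.ndarray
    t_f: float                      # time of the last successful exchange
    events_to_stable: int           # event index of the last successful exchange
    total_events: int
    successful_exchanges: int
    termination_reason: str         # window | time_window | max_events | exhausted
    trajectory: list[tuple[float, np.ndarray]] = field(default_factory=list)


def init_opinions(n_nodes: int, rng) -> OpinionState:
    """I.i.d. Uniform[0, 1] opinions."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    gen = rng if isinstance(rng, Generator) else default_rng(rng)
    return OpinionState(opinions=gen.random(n_nodes))


def attempt_exchange(
    state: OpinionState, i: int, j: int, d: float, mu: float
) -> bool:
    """Apply one pairwise exchange attempt; True if the gate |x_i-x_j| < d
    passed and the update changed at least one opinion."""
    if i == j:
        raise ValueError("a node cannot exchange with itself")
    x = state.opinions
    xi = x[i]
    xj = x[j]
    dx = xi - xj
    if -d < dx < d:
        ni = xi - mu * dx
        nj = xj + mu * dx
        if ni != xi or nj != xj:
            x[i] = ni
            x[j] = nj
            return True
    return False


def run_temporal(
    network: StaticNetwork,
    schedule: ActivationSchedule,
    config: SimulationConfig,
    rng=None,
    state: Optional[OpinionState] = None,
    trajectory_every: int = 0,
) -> SimulationResult:
    """Drive the opinion dynamics with the schedule's activation stream.

    Burn-in is assumed to have been applied to the schedule already.
    Events are processed strictly in time order; the run ends via the
    no-success window(s), schedule exhaustion, or the ``max_events`` cap.
    """
    if schedule.links != list(network.edges):
        raise ValueError("schedule and network disagree on the link set")
    if state is None:
        gen = rng if isinstance(rng, Generator) else default_rng(
            rng if rng is not None else config.seed
        )
        state = init_opinions(network.n_nodes, gen)
    x = state.opinions.tolist()
    ua = [e[0] for e in schedule.links]
    va = [e[1] for e in schedule.links]
    d = config.d
    mu = config.mu
    atol = config.quiescence_atol
    stop_events = config.stop_window if config.stop_window is not None else network.n_nodes
    stop_time = config.stop_time_window
    max_events = config.max_events

    events = 0
    succ = 0
    fails = 0
    t_last = schedule.current_time
    t_f = 0.0
    ev_stable = 0
    reason = "exhausted"
    trajectory: list[tuple[float, np.ndarray]] = []
    done = False

    for times, linkidx in schedule.iter_chunks():
        tl = times.tolist()
        ll = linkidx.tolist()
        consumed = 0
        for k in range(len(tl)):
            li = ll[k]
            t = tl[k]
            consumed += 1
            events += 1
            xi = x[ua[li]]
            xj = x[va[li]]
            dx = xi - xj
            if (-d < dx < d) and (dx > atol or dx < -atol):
                x[ua[li]] = xi - mu * dx
                x[va[li]] = xj + mu * dx
                succ += 1
                fails = 0
                t_last = t
                t_f = t
                ev_stable = events
            else:
                fails += 1
                if stop_events is not None and fails >= stop_events:
                    reason = "window"
                    done = True
                elif stop_time is not None and t - t_last >= stop_time:
                    reason = "time_window"
                    done = True
            if trajectory_every and events % trajectory_every == 0:
                trajectory.append((t, np.array(x)))
            if done or events >= max_events:
                if not done:
                    reason = "max_events"
                    done = True
                break
        schedule.mark_consumed(consumed, tl[consumed - 1] if consumed else schedule.current_time)
        if done:
            break

    state.opinions = np.array(x)
    state.total_events += events
    state.successful_exchanges += succ
    state.last_success_event = ev_stable
    return SimulationResult(
        final_opinions=state.opinions,
        t_f=t_f,
        events_to_stable=ev_stable,
        total_events=events,
        successful_exchanges=succ,
        termination_reason=reason,
        trajectory=trajectory,
    )


def run_static_baseline(
    network: StaticNetwork,
    config: SimulationConfig,
    rng=None,
    state: Optional[OpinionState] = None,
) -> SimulationResult:
    """Classical Deffuant dynamics: one uniformly random edge per step.

    The stopping rule counts discrete steps in place of activations; the
    reported T_f is the step index of the last successful exchange.
    """
    if network.n_edges == 0:
        raise ValueError("network has no edges")
    gen = rng if isinstance(rng, Generator) else default_rng(
        rng if rng is not None else config.seed
    )
    if state is None:
        state = init_opinions(network.n_nodes, gen)
    x = state.opinions.tolist()
    ua = [e[0] for e in network.edges]
    va = [e[1] for e in network.edges]
    n_edges = network.n_edges
    d = config.d
    mu = config.mu
    atol = config.quiescence_atol
    stop = config.stop_window if config.stop_window is not None else network.n_nodes
    max_events = config.max_events

    steps = 0
    succ = 0
    fails = 0
    t_f = 0.0
    ev_stable = 0
    reason = "max_events"
    buf: list[int] = []
    bp = 0
    while steps < max_events:
        if bp == len(buf):
            buf = gen.integers(0, n_edges, size=1 << 15).tolist()
            bp = 0
        li = buf[bp]
        bp += 1
        steps += 1
        xi = x[ua[li]]
        xj = x[va[li]]
        dx = xi - xj
        if (-d < dx < d) and (dx > atol or dx < -atol):
            x[ua[li]] = xi - mu * dx
            x[va[li]] = xj + mu * dx
            succ += 1
            fails = 0
            t_f = float(steps)
            ev_stable = steps
        else:
            fails += 1
            if fails >= stop:
                reason = "window"
                break

    state.opinions = np.array(x)
    state.total_events += steps
    state.successful_exchanges += succ
    state.last_success_event = ev_stable
    return SimulationResult(
        final_opinions=state.opinions,
        t_f=t_f,
        events_to_stable=ev_stable,
        total_events=steps,
        successful_exchanges=succ,
        termination_reason=reason,
    )
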