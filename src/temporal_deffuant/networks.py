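"""Static social-network substrates and their structural statistics.

Three generators are provided: Erdős–Rényi (homogeneous random ties),
Watts–Strogatz (ring lattice with rewiring: high local clustering, short
paths), and an attribute-fitness preferential-attachment model in which a
newly arrived individual J attaches to an existing individual i with
probability proportional to

    phi_J(i) ∝ k_i * exp(-beta * |theta_J - theta_i|),

where k_i is the degree, theta in [0, 1] is a scalar attribute (e.g. a
normalised age) and beta >= 0 controls attribute homophily.  beta = 0
recovers pure (Barabási–Albert) preferential attachment; large beta sweeps
links from hubs towards attribute-similar peers, producing clustering and
community structure.

A degree-preserving double-edge-swap rewiring is included as the matched
configuration-model null, plus the structural statistics used to compare
substrates: mean degree, clustering coefficient, normalised betweenness,
modularity of a detected partition, and degree assortativity.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

__all__ = [
    "StaticNetwork",
    "NetworkStats",
    "generate_er",
    "generate_ws",
    "generate_fitness",
    "rewire_to_configuration",
    "compute_stats",
]


@dataclass
class StaticNetwork:
    """Undirected simple graph with an optional per-node attribute.

    Nodes are labelled 0..n_nodes-1.  ``attribute`` is present iff the
    network was grown by the fitness model (or supplied by the user).
    """

    n_nodes: int
    edges: list[tuple[int, int]]
    attribute: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        seen = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise ValueError(f"edge ({u},{v}) outside 0..{self.n_nodes - 1}")
            key = (u, v) if u < v else (v, u)
            if key in seen:
                raise ValueError(f"duplicate edge ({u},{v})")
            seen.add(key)
        self.edges = sorted(seen)
        if self.attribute is not None:
            self.attribute = np.asarray(self.attribute, dtype=float)
            if self.attribute.shape != (self.n_nodes,):
                raise ValueError("attribute must have one value per node")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        if self.attribute is not None:
            nx.set_node_attributes(
                g, dict(enumerate(self.attribute.tolist())), "theta"
            )
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "StaticNetwork":
        mapping = {node: i for i, node in enumerate(sorted(g.nodes()))}
        edges = [(mapping[u], mapping[v]) for u, v in g.edges()]
        theta = nx.get_node_attributes(g, "theta")
        attribute = None
        if len(theta) == g.number_of_nodes() and g.number_of_nodes() > 0:
            attribute = np.array([theta[n] for n in sorted(g.nodes())])
        return cls(g.number_of_nodes(), edges, attribute)


@dataclass
class NetworkStats:
    """Structural summary of a substrate.

    ``assortativity`` is None for degenerate (e.g. regular) graphs where
    the degree correlation is undefined.
    """

    mean_degree: float
    mean_clustering: float
    mean_betweenness: float
    modularity: float
    assortativity: Optional[float]
    degree_distribution: dict[int, int] = field(default_factory=dict)


def _rng(seed) -> Generator:
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed)


def generate_er(n_nodes: int, mean_degree: float, seed) -> StaticNetwork:
    """Erdős–Rényi G(n, p) with p chosen to match the requested mean degree."""
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if not 0 <= mean_degree <= n_nodes - 1:
        raise ValueError("mean_degree must be in [0, n_nodes-1]")
    p = mean_degree / (n_nodes - 1)
    g = nx.fast_gnp_random_graph(n_nodes, p, seed=_rng(seed))
    return StaticNetwork(n_nodes, list(g.edges()))


def generate_ws(n_nodes: int, k_nn: int, rewire_prob: float, seed) -> StaticNetwork:
    """Watts–Strogatz ring lattice (k_nn nearest neighbours) with rewiring q."""
    if k_nn % 2 != 0:
        raise ValueError("k_nn must be even")
    if k_nn >= n_nodes:
        raise ValueError("k_nn must be < n_nodes")
    if not 0 <= rewire_prob <= 1:
        raise ValueError("rewire_prob must be in [0, 1]")
    g = nx.watts_strogatz_graph(n_nodes, k_nn, rewire_prob, seed=_rng(seed))
    return StaticNetwork(n_nodes, list(g.edges()))


def generate_fitness(
    n_nodes: int,
    links_per_node: int = 3,
    beta: float = 0.0,
    seed=None,
    attribute: Optional[np.ndarray] = None,
) -> StaticNetwork:
    """Grow an attribute-fitness preferential-attachment network.

    Growth starts from a complete graph on ``links_per_node`` nodes; every
    subsequent node attaches to ``links_per_node`` distinct existing nodes,
    drawn without replacement with probability proportional to
    ``k_i * exp(-beta |theta_J - theta_i|)`` (weights renormalised after
    each draw so the graph stays simple).  Node attributes theta are i.i.d.
    Uniform[0, 1] unless supplied.
    """
    m = links_per_node
    if m < 1:
        raise ValueError("links_per_node must be >= 1")
    if m >= n_nodes:
        raise ValueError("links_per_node must be < n_nodes")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    rng = _rng(seed)
    if attribute is None:
        theta = rng.random(n_nodes)
    else:
        theta = np.asarray(attribute, dtype=float)
        if theta.shape != (n_nodes,):
            raise ValueError("attribute must have one value per node")

    edges: list[tuple[int, int]] = [
        (i, j) for i in range(m) for j in range(i + 1, m)
    ]
    deg = np.zeros(n_nodes, dtype=float)
    deg[:m] = m - 1
    if m == 1:
        # a single seed node has degree 0; give it unit weight so the
        # first attachment is well defined
        deg[0] = 1.0

    for new in range(m, n_nodes):
        w = deg[:new] * np.exp(-beta * np.abs(theta[new] - theta[:new]))
        if m == 1 and new == 1:
            w = np.ones(1)
        targets: list[int] = []
        for _ in range(m):
            total = w.sum()
            if total <= 0:
                # all remaining weights zero (can happen only with extreme
                # beta underflow): fall back to uniform over the remainder
                w = np.where(w > 0, w, 0.0)
                remaining = [i for i in range(new) if i not in targets]
                tgt = int(rng.choice(remaining))
            else:
                tgt = int(rng.choice(new, p=w / total))
            targets.append(tgt)
            w[tgt] = 0.0
        for tgt in targets:
            edges.append((tgt, new))
            deg[tgt] += 1
        deg[new] = m
    return StaticNetwork(n_nodes, edges, attribute=theta)


def rewire_to_configuration(
    network: StaticNetwork, n_swaps: Optional[int] = None, seed=None,
    max_tries_factor: int = 200,
) -> StaticNetwork:
    """Degree-preserving randomisation by double edge swaps.

    Repeatedly picks two distinct edges (a,b), (c,d) uniformly at random and
    proposes the swap to (a,d), (c,b); proposals creating a self-loop or a
    duplicate edge are rejected and redrawn.  ``n_swaps`` accepted swaps are
    performed (default 10x the edge count, a standard mixing heuristic).
    Gives up after ``max_tries_factor * n_swaps`` proposals so that rigid
    graphs (e.g. a triangle, where every proposal is rejected) terminate.
    """
    if network.n_edges < 2:
        raise ValueError("need at least 2 edges to swap")
    rng = _rng(seed)
    edges = [list(e) for e in network.edges]
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    edge_set = {tuple(sorted(e)) for e in network.edges}
    accepted = 0
    tries = 0
    max_tries = max_tries_factor * max(n_swaps, 1)
    n_edges = len(edges)
    while accepted < n_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        # swap one end of each tie: (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(tuple(sorted((a, b))))
        edge_set.discard(tuple(sorted((c, d))))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = [a, d]
        edges[j] = [c, b]
        accepted += 1
    if accepted < n_swaps:
        warnings.warn(
            f"only {accepted}/{n_swaps} swaps accepted after {tries} proposals",
            stacklevel=2,
        )
    return StaticNetwork(
        network.n_nodes,
        [tuple(e) for e in edge_set],
        attribute=None if network.attribute is None else network.attribute.copy(),
    )


def mean_clustering(network: StaticNetwork) -> float:
    """Mean of the per-node clustering coefficient 2 e_i / (k_i (k_i - 1)).

    Nodes with degree < 2 contribute 0.
    """
    return nx.average_clustering(network.to_networkx(), count_zeros=True)


def modularity(network: StaticNetwork, seed: int = 0) -> float:
    """Modularity Q of the partition found by Louvain maximisation."""
    g = network.to_networkx()
    if g.number_of_edges() == 0:
        return 0.0
    communities = nx.community.louvain_communities(g, seed=seed)
    return nx.community.modularity(g, communities)


def attribute_partition(network: StaticNetwork, n_bins: int = 5) -> list[set[int]]:
    """Partition nodes into equal-width attribute bins (default quintiles)."""
    if network.attribute is None:
        raise ValueError("network carries no attribute")
    bins = np.minimum((network.attribute * n_bins).astype(int), n_bins - 1)
    groups = [set(np.nonzero(bins == b)[0].tolist()) for b in range(n_bins)]
    return [grp for grp in groups if grp]


def assortativity(network: StaticNetwork) -> Optional[float]:
    """Pearson correlation of degrees across edge endpoints (both orientations).

    Returns None when undefined (zero degree variance at either end, e.g.
    regular graphs).
    """
    deg = network.degrees()
    if network.n_edges == 0:
        return None
    a = np.array([deg[u] for u, v in network.edges], dtype=float)
    b = np.array([deg[v] for u, v in network.edges], dtype=float)
    x = np.concatenate([a, b])
    y = np.concatenate([b, a])
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return None
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def compute_stats(
    network: StaticNetwork,
    community_method: str = "louvain",
    seed: int = 0,
    include_betweenness: bool = True,
) -> NetworkStats:
    """All structural statistics of a substrate.

    Betweenness is shortest-path betweenness, normalised by (n-1)(n-2)/2,
    endpoints excluded.  ``community_method`` selects how the partition
    behind Q is obtained: "louvain" or "greedy" (Clauset-Newman-Moore)
    maximise modularity; "attribute" evaluates Q on the fixed partition of
    nodes into attribute quintiles (meaningful only for attribute-carrying
    networks — it is ~0 whenever ties ignore the attribute, which makes it
    the natural yardstick for attribute homophily).
    """
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    g = network.to_networkx()
    deg = network.degrees()
    if include_betweenness and network.n_nodes > 2:
        bc = nx.betweenness_centrality(g, normalized=True, endpoints=False)
        mean_b = float(np.mean(list(bc.values())))
    else:
        mean_b = 0.0
    if g.number_of_edges() > 0:
        if community_method == "louvain":
            comms = nx.community.louvain_communities(g, seed=seed)
        elif community_method == "greedy":
            comms = nx.community.greedy_modularity_communities(g)
        elif community_method == "attribute":
            comms = attribute_partition(network)
        else:
            raise ValueError(f"unknown community_method {community_method!r}")
        q = nx.community.modularity(g, comms)
    else:
        q = 0.0
    return NetworkStats(
        mean_degree=network.mean_degree,
        mean_clustering=nx.average_clustering(g, count_zeros=True),
        mean_betweenness=mean_b,
        modularity=q,
        assortativity=assortativity(network),
        degree_distribution=dict(Counter(deg.tolist())),
    )
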