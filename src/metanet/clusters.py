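"""Density clustering (MCODE-style) and hub-node detection.

Clusters are dense, connected node subsets found by the three MCODE stages:
k-core-based vertex weighting, seeded greedy complex prediction, and
haircut/fluff post-processing. Hubs are high-degree candidates whose removal
significantly shifts the network's degree distribution, judged by a
Kruskal-Wallis rank test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
from scipy import stats

from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "HubReport",
    "mcode_cluster",
    "hub_candidates",
    "default_top_k",
    "hub_test",
]


@dataclass(frozen=True)
class Cluster:
    """A scored dense subgraph: sorted member labels, its seed, and the
    MCODE score (subgraph density x member count)."""

    members: tuple
    seed: str
    score: float

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HubReport:
    node: str
    degree: int
    p_value: float
    is_hub: bool
    statistic: float = 0.0


def _vertex_weight(net: nx.Graph, v, k_core: int) -> float:
    """Core-clustering coefficient of v's k_core-filtered closed neighborhood
    times that neighborhood's highest k-core number."""
    closed = list(net[v]) + [v]
    sub = net.subgraph(closed)
    core = nx.k_core(sub, k_core)
    n = core.number_of_nodes()
    if n < 2:
        return 0.0
    k_max = max(nx.core_number(core).values())
    density = 2.0 * core.number_of_edges() / (n * (n - 1))
    return k_max * density


def mcode_cluster(
    net: nx.Graph,
    k_core: int = 2,
    node_score_cutoff: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.1,
) -> list[Cluster]:
    """Detect dense clusters by the three MCODE stages.

    Stage 1 weights each vertex by the density of the ``k_core``-filtered
    closed neighborhood times its highest core number. Stage 2 seeds at the
    highest-weight unassigned vertex and greedily admits the seed's
    unassigned neighbors whose weight is >= (1 - node_score_cutoff) x seed
    weight. Stage 3 optionally fluffs (adds unassigned neighbors whose
    closed-neighborhood density exceeds ``fluff_density``) and haircuts
    (iteratively strips members with fewer than 2 in-cluster edges).

    Clusters have >= 3 members, induce a connected subgraph, are mutually
    disjoint, and are returned sorted by score descending. Ties in seeding
    and ordering break lexicographically, so results are deterministic.
    """
    if k_core < 2:
        raise ParameterError(f"k_core must be >= 2, got {k_core}")
    if not 0.0 <= node_score_cutoff <= 1.0:
        raise ParameterError(f"node_score_cutoff must be in [0, 1], got {node_score_cutoff}")
    if net.number_of_nodes() == 0:
        return []

    weights = {v: _vertex_weight(net, v, k_core) for v in net}
    order = sorted(net, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    clusters: list[Cluster] = []

    for seed in order:
        if seed in assigned or weights[seed] <= 0:
            continue
        cutoff = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed} | {
            u for u in net[seed] if u not in assigned and weights[u] >= cutoff
        }

        if fluff:
            for m in sorted(members, key=str):
                for u in net[m]:
                    if u in members or u in assigned:
                        continue
                    closed = list(net[u]) + [u]
                    sub_u = net.subgraph(closed)
                    n_u = sub_u.number_of_nodes()
                    dens = (
                        2.0 * sub_u.number_of_edges() / (n_u * (n_u - 1))
                        if n_u > 1
                        else 0.0
                    )
                    if dens > fluff_density:
                        members.add(u)

        sub = net.subgraph(members).copy()
        if haircut:
            while True:
                trim = [v for v in sub if sub.degree(v) < 2]
                if not trim:
                    break
                sub.remove_nodes_from(trim)
        if seed not in sub:
            assigned.add(seed)
            continue
        component = nx.node_connected_component(sub, seed)
        sub = sub.subgraph(component)
        if sub.number_of_nodes() < 3:
            assigned.add(seed)
            continue
        n = sub.number_of_nodes()
        density = 2.0 * sub.number_of_edges() / (n * (n - 1))
        clusters.append(
            Cluster(members=tuple(sorted(sub.nodes, key=str)), seed=seed, score=density * n)
        )
        assigned |= set(sub.nodes)

    clusters.sort(key=lambda c: (-c.score, -len(c.members), c.members))
    return clusters


def default_top_k(n_nodes: int) -> int:
    """Default hub-candidate pool size: max(5, 5% of nodes)."""
    return max(5, math.ceil(0.05 * n_nodes))


def hub_candidates(net: nx.Graph, top_k: int | None = None) -> list:
    """The ``top_k`` most connected nodes (degree descending, ties by label)."""
    if top_k is None:
        top_k = default_top_k(net.number_of_nodes())
    if top_k < 1:
        raise ParameterError(f"top_k must be >= 1, got {top_k}")
    if top_k > net.number_of_nodes():
        logger.warning(
            "hub_candidates: top_k=%d exceeds node count %d; truncating",
            top_k,
            net.number_of_nodes(),
        )
        top_k = net.number_of_nodes()
    ranked = sorted(net, key=lambda v: (-net.degree(v), str(v)))
    return ranked[:top_k]


def hub_test(net: nx.Graph, node, alpha: float = 0.05, metric=None) -> HubReport:
    """Kruskal-Wallis test of the degree distribution before vs after deleting
    ``node``.

    Both samples are the per-node metric values of all *other* nodes — once
    in the intact network, once after the deletion — so they differ only
    through the deleted node's incident edges. The metric defaults to degree
    but any ``callable(graph) -> {node: value}`` may be supplied.
    ``is_hub`` is True when p <= alpha.
    """
    if node not in net:
        raise KeyError(f"node {node!r} not in network")
    if net.number_of_nodes() < 5:
        raise ParameterError("hub_test needs a network with >= 5 nodes")
    if metric is None:
        metric = lambda g: dict(g.degree())  # noqa: E731

    others = [v for v in net if v != node]
    before_map = metric(net)
    reduced = net.subgraph(others)
    after_map = metric(reduced)
    before = [before_map[v] for v in others]
    after = [after_map[v] for v in others]

    if before == after:
        return HubReport(node=node, degree=net.degree(node), p_value=1.0, is_hub=False)
    try:
        res = stats.kruskal(before, after)
        statistic, p_value = float(res.statistic), float(res.pvalue)
    except ValueError:  # all values identical across both samples
        statistic, p_value = 0.0, 1.0
    return HubReport(
        node=node,
        degree=net.degree(node),
        p_value=p_value,
        is_hub=bool(p_value <= alpha),
        statistic=statistic,
    )
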