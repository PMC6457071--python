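"""Network comparison: Jaccard similarity trees, alignment quality scores,
global/local topology tables, and a 4-node motif census with a
degree-preserving randomisation null.

All comparisons assume networks over shared taxon labels, so alignment
defaults to the identity mapping on the common label set rather than a
search over mappings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentScores",
    "GlobalProperties",
    "MotifCensus",
    "MOTIF_CLASSES",
    "jaccard_similarity",
    "similarity_tree",
    "alignment_scores",
    "global_properties",
    "local_properties",
    "motif_census",
    "degree_preserving_rewire",
    "connected_induced_subgraphs",
]

#: the six connected 4-node isomorphism classes, keyed by induced degree sequence
MOTIF_CLASSES = ("path", "star", "cycle", "tadpole", "diamond", "clique")

_DEGSEQ_TO_CLASS = {
    (1, 1, 2, 2): "path",
    (1, 1, 1, 3): "star",
    (2, 2, 2, 2): "cycle",
    (1, 2, 2, 3): "tadpole",
    (2, 2, 3, 3): "diamond",
    (3, 3, 3, 3): "clique",
}


# ---------------------------------------------------------------------------
# Jaccard similarity and similarity trees


def _element_set(net: nx.Graph, on: str) -> set:
    if on == "nodes":
        return set(net.nodes)
    if on == "edges":
        return {frozenset(e) for e in net.edges}
    raise ParameterError(f"unknown comparison element {on!r} (expected nodes or edges)")


def jaccard_similarity(a: nx.Graph, b: nx.Graph, on: str = "nodes") -> float:
    """|intersection| / |union| of node-label or edge sets; 1.0 when both empty."""
    sa, sb = _element_set(a, on), _element_set(b, on)
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


def similarity_tree(nets, on: str = "nodes") -> str:
    """Average-linkage hierarchical clustering of networks on 1 - Jaccard,
    returned as a newick string with branch lengths equal to merge-height
    differences.

    ``nets`` is a mapping name -> graph or an iterable of (name, graph)
    pairs; at least 2 networks with distinct names are required.
    """
    items = list(nets.items()) if hasattr(nets, "items") else list(nets)
    names = [n for n, _ in items]
    if len(set(names)) != len(names):
        raise ParameterError(f"duplicate network names: {names}")
    if len(items) < 2:
        raise ParameterError("similarity_tree needs at least 2 networks")
    n = len(items)
    dist = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = 1.0 - jaccard_similarity(items[i][1], items[j][1], on=on)
        dist[i, j] = dist[j, i] = d
    z = linkage(squareform(dist, checks=False), method="average")
    root = to_tree(z)

    def render(node) -> str:
        if node.is_leaf():
            return names[node.id].replace(" ", "_")
        left = render(node.left)
        right = render(node.right)
        ll = node.dist - node.left.dist
        rl = node.dist - node.right.dist
        return f"({left}:{ll:.10g},{right}:{rl:.10g})"

    return render(root) + ";"


# ---------------------------------------------------------------------------
# alignment quality


@dataclass(frozen=True)
class AlignmentScores:
    """Edge correctness, induced conserved structure, symmetric substructure."""

    ec: float
    ics: float
    s3: float


def alignment_scores(a: nx.Graph, b: nx.Graph, mapping: dict | None = None) -> AlignmentScores:
    """EC / ICS / S3 of aligning ``a`` into ``b`` under ``mapping``.

    The mapping must be injective; by default it is the identity on the
    shared label set, with ``a`` restricted to the mapped nodes. With
    conserved = edges of ``a`` whose images are adjacent in ``b`` and
    induced = edges of ``b`` among image nodes:

        EC  = conserved / |E_a|
        ICS = conserved / induced
        S3  = conserved / (|E_a| + induced - conserved)

    An empty mapped edge set yields (1, 1, 1) with a warning (vacuously
    perfect); an empty induced set likewise gives ICS = 1.
    """
    if mapping is None:
        mapping = {v: v for v in a.nodes if v in b}
    if len(set(mapping.values())) != len(mapping):
        raise ParameterError("alignment mapping must be injective")
    for u, v in mapping.items():
        if u not in a or v not in b:
            raise ParameterError(f"mapping entry {u!r} -> {v!r} not in the networks")

    mapped_edges = [
        (u, v) for u, v in a.edges if u in mapping and v in mapping
    ]
    conserved = sum(1 for u, v in mapped_edges if b.has_edge(mapping[u], mapping[v]))
    image = set(mapping.values())
    induced = b.subgraph(image).number_of_edges()

    if not mapped_edges:
        warnings.warn("alignment has no source edges; scores defined as 1.0", stacklevel=2)
        return AlignmentScores(1.0, 1.0, 1.0)
    ec = conserved / len(mapped_edges)
    if induced == 0:
        warnings.warn("alignment image induces no edges; ICS defined as 1.0", stacklevel=2)
        ics = 1.0
    else:
        ics = conserved / induced
    s3 = conserved / (len(mapped_edges) + induced - conserved)
    return AlignmentScores(ec, ics, s3)


# ---------------------------------------------------------------------------
# global and local topological properties


@dataclass(frozen=True)
class GlobalProperties:
    n_nodes: int
    n_edges: int
    density: float
    clustering_coefficient: float
    avg_path_length: float


def global_properties(net: nx.Graph) -> GlobalProperties:
    """Node/edge counts, density, mean local clustering, and the average
    shortest-path length of the largest connected component (networks here
    are frequently disconnected)."""
    n = net.number_of_nodes()
    if n == 0:
        return GlobalProperties(0, 0, 0.0, 0.0, 0.0)
    clustering = nx.average_clustering(net) if n > 0 else 0.0
    apl = 0.0
    components = list(nx.connected_components(net))
    largest = max(components, key=len)
    if len(components) > 1:
        logger.info(
            "global_properties: %d components; path length restricted to the "
            "largest (%d nodes)",
            len(components),
            len(largest),
        )
    if len(largest) > 1:
        apl = nx.average_shortest_path_length(net.subgraph(largest))
    return GlobalProperties(
        n_nodes=n,
        n_edges=net.number_of_edges(),
        density=nx.density(net),
        clustering_coefficient=clustering,
        avg_path_length=apl,
    )


def local_properties(net: nx.Graph) -> pd.DataFrame:
    """Per-node table of coreness, degree, eigenvector centrality (scaled to
    max 1), eccentricity (per connected component), betweenness (raw path
    counts), and degree centrality."""
    columns = [
        "coreness",
        "degree",
        "eigenvector_centrality",
        "eccentricity",
        "betweenness",
        "degree_centrality",
    ]
    nodes = sorted(net.nodes, key=str)
    if not nodes:
        return pd.DataFrame(columns=columns)
    n = len(nodes)
    coreness = nx.core_number(net)
    if net.number_of_edges() > 0:
        eig = nx.eigenvector_centrality_numpy(net)
        peak = max(abs(v) for v in eig.values())
        eig = {v: abs(val) / peak for v, val in eig.items()}
    else:
        eig = {v: 0.0 for v in nodes}
    ecc: dict = {}
    for comp in nx.connected_components(net):
        ecc.update(nx.eccentricity(net.subgraph(comp)))
    btw = nx.betweenness_centrality(net, normalized=False)
    return pd.DataFrame(
        {
            "coreness": [coreness[v] for v in nodes],
            "degree": [net.degree(v) for v in nodes],
            "eigenvector_centrality": [eig[v] for v in nodes],
            "eccentricity": [ecc[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "degree_centrality": [net.degree(v) / (n - 1) if n > 1 else 0.0 for v in nodes],
        },
        index=nodes,
    )


# ---------------------------------------------------------------------------
# motif census


def connected_induced_subgraphs(net: nx.Graph, k: int = 4) -> list[tuple]:
    """Enumerate each connected induced k-node subgraph exactly once (ESU)."""
    order = sorted(net.nodes, key=str)
    idx = {v: i for i, v in enumerate(order)}
    adj = {v: set(net[v]) for v in net}
    out: list[tuple] = []

    def extend(sub: list, ext: set, root) -> None:
        if len(sub) == k:
            out.append(tuple(sub))
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            nbr_sub = set(sub)
            for u in sub:
                nbr_sub |= adj[u]
            new_ext = ext | {
                u for u in adj[w] if idx[u] > idx[root] and u not in nbr_sub
            }
            extend(sub + [w], new_ext, root)

    for v in order:
        extend([v], {u for u in adj[v] if idx[u] > idx[v]}, v)
    return out


def _classify(net: nx.Graph, quad: tuple) -> str:
    degseq = tuple(
        sorted(sum(1 for u in quad if net.has_edge(v, u)) for v in quad)
    )
    return _DEGSEQ_TO_CLASS[degseq]


def degree_preserving_rewire(net: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """Randomise edges by double edge swaps (10 x |E| attempts), preserving
    every node's degree exactly. Graphs too small or too constrained to swap
    are returned unchanged (a copy)."""
    rewired = net.copy()
    n_edges = rewired.number_of_edges()
    if n_edges < 2 or rewired.number_of_nodes() < 4:
        return rewired
    nswap = 10 * n_edges
    seed = int(rng.integers(0, 2**31 - 1))
    try:
        nx.double_edge_swap(rewired, nswap=nswap, max_tries=100 * nswap, seed=seed)
    except nx.NetworkXException:
        # swaps performed so far are kept; degrees remain intact
        logger.debug("degree_preserving_rewire: swap budget exhausted early")
    return rewired


@dataclass
class MotifCensus:
    """Counts, frequencies and randomisation z-scores of the six connected
    4-node subgraph classes."""

    counts: dict = field(default_factory=dict)
    frequency: dict = field(default_factory=dict)
    z_score: dict = field(default_factory=dict)
    n_subgraphs: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": [self.counts.get(c, 0) for c in MOTIF_CLASSES],
                "frequency": [self.frequency.get(c, 0.0) for c in MOTIF_CLASSES],
                "z_score": [self.z_score.get(c, 0.0) for c in MOTIF_CLASSES],
            },
            index=list(MOTIF_CLASSES),
        )


def _census_counts(net: nx.Graph) -> dict:
    counts = {c: 0 for c in MOTIF_CLASSES}
    for quad in connected_induced_subgraphs(net, 4):
        counts[_classify(net, quad)] += 1
    return counts


def motif_census(net: nx.Graph, n_random: int = 100, seed: int = 0) -> MotifCensus:
    """Census of connected 4-node induced subgraphs with z-scores against
    ``n_random`` degree-preserving rewired replicates.

    Frequencies are class count / total subgraph count; z-scores use the
    rewired ensemble's mean and (sample) standard deviation, with z = 0
    where the ensemble shows no variance. Networks with fewer than 4 nodes
    yield an empty census with a warning.
    """
    if net.number_of_nodes() < 4:
        logger.warning("motif_census: fewer than 4 nodes; empty census")
        return MotifCensus(
            counts={c: 0 for c in MOTIF_CLASSES},
            frequency={c: 0.0 for c in MOTIF_CLASSES},
            z_score={c: 0.0 for c in MOTIF_CLASSES},
            n_subgraphs=0,
        )
    counts = _census_counts(net)
    total = sum(counts.values())
    frequency = {c: (counts[c] / total if total else 0.0) for c in MOTIF_CLASSES}

    rng = np.random.default_rng(seed)
    ensemble = {c: [] for c in MOTIF_CLASSES}
    for _ in range(n_random):
        rand_counts = _census_counts(degree_preserving_rewire(net, rng))
        for c in MOTIF_CLASSES:
            ensemble[c].append(rand_counts[c])
    z_score = {}
    for c in MOTIF_CLASSES:
        arr = np.asarray(ensemble[c], dtype=float)
        std = arr.std(ddof=1) if len(arr) > 1 else 0.0
        z_score[c] = float((counts[c] - arr.mean()) / std) if std > 0 else 0.0
    return MotifCensus(
        counts=counts, frequency=frequency, z_score=z_score, n_subgraphs=total
    )
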