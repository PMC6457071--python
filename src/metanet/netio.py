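"""Network and table serialisation: GraphML, weighted edge lists, cluster
and hub tables."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "write_network",
    "read_network",
    "write_edge_list",
    "write_clusters",
    "write_hub_reports",
]


def _graphml_safe(graph: nx.Graph) -> nx.Graph:
    """Copy with non-scalar graph attributes JSON-encoded (GraphML only
    stores scalars)."""
    out = graph.copy()
    for key, value in list(out.graph.items()):
        if not isinstance(value, (str, int, float, bool)):
            out.graph[key] = json.dumps(value)
    return out


def write_network(graph: nx.Graph, path: str | Path) -> None:
    """Write a network as GraphML; edge attributes (weight, sign, kind,
    p_value, fs_weight) are preserved with their types."""
    nx.write_graphml(_graphml_safe(graph), str(path))


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path), node_type=str)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Three-column TSV: source, target, weight (sorted, deterministic)."""
    rows = [
        (u, v, graph.edges[u, v].get("weight", 1.0))
        for u, v in sorted((tuple(sorted(e)) for e in graph.edges))
    ]
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w:.6g}\n")


def write_clusters(clusters, path: str | Path) -> None:
    """Cluster table TSV: cluster id, score, size, seed, comma-joined members."""
    frame = pd.DataFrame(
        {
            "cluster": range(1, len(clusters) + 1),
            "score": [c.score for c in clusters],
            "size": [len(c.members) for c in clusters],
            "seed": [c.seed for c in clusters],
            "members": [",".join(map(str, c.members)) for c in clusters],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_hub_reports(reports, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "node": [r.node for r in reports],
            "degree": [r.degree for r in reports],
            "p_value": [r.p_value for r in reports],
            "is_hub": [r.is_hub for r in reports],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
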