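"""FS-Weight: neighborhood-overlap scoring of direct and indirect taxon pairs.

Two taxa that share many network neighbors are likely functionally
associated even when no direct correlation links them — in a microbial
community, members of the same metabolic chain can be coupled through a
shared partner rather than pairwise. The FS-Weight score of nodes u, v is

    S(u, v) = [2 n_uv / (n_u\\v + 2 n_uv + lam_u)] *
              [2 n_uv / (n_v\\u + 2 n_uv + lam_v)]

where ``n_uv = |N_u & N_v|``, ``n_u\\v = |N_u - N_v|``, ``N_x`` is the
neighbor set of x (including x itself when ``include_self``), and
``lam_x = max(0, n_avg - |N_x|)`` penalises nodes with fewer neighbors than
the network average (0 when the pseudocount is off). S is symmetric and
lies in [0, 1].

Scoring is purely topological: correlation weights decide which edges exist
in the input network but do not enter S.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = ["FSWeightParams", "fsweight_score", "build_fsweight_network"]

#: default score thresholds at the two taxonomic levels
LEVEL_FSW_THRESHOLDS = {"genus": 0.5, "otu": 0.7}


@dataclass(frozen=True)
class FSWeightParams:
    """Parameters for FS-Weight scoring.

    threshold
        Minimum score for an edge (direct kept / indirect added); default
        0.5 at genus level, 0.7 at OTU level.
    include_self
        Whether each node's neighborhood includes the node itself.
    pseudocount
        Whether the average-neighborhood-size correction ``lam`` is applied.
    """

    threshold: float = 0.5
    include_self: bool = True
    pseudocount: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ParameterError(f"FS-Weight threshold must be in [0, 1], got {self.threshold}")


def _neighborhoods(net: nx.Graph, include_self: bool) -> dict:
    nbhd = {}
    for v in net:
        n = set(net[v])
        if include_self:
            n.add(v)
        nbhd[v] = n
    return nbhd


def _score(nu: set, nv: set, n_avg: float, pseudocount: bool) -> float:
    n_uv = len(nu & nv)
    if n_uv == 0:
        return 0.0
    lam_u = max(0.0, n_avg - len(nu)) if pseudocount else 0.0
    lam_v = max(0.0, n_avg - len(nv)) if pseudocount else 0.0
    f_u = 2 * n_uv / (len(nu - nv) + 2 * n_uv + lam_u)
    f_v = 2 * n_uv / (len(nv - nu) + 2 * n_uv + lam_v)
    return f_u * f_v


def fsweight_score(
    net: nx.Graph, u, v, params: FSWeightParams | None = None
) -> float:
    """FS-Weight score of the (unordered) pair ``u, v`` in ``net``."""
    params = params or FSWeightParams()
    if u not in net:
        raise KeyError(f"node {u!r} not in network")
    if v not in net:
        raise KeyError(f"node {v!r} not in network")
    if u == v:
        raise ParameterError("FS-Weight is defined for distinct node pairs")
    nbhd = _neighborhoods(net, params.include_self)
    n_avg = sum(len(n) for n in nbhd.values()) / len(nbhd)
    return _score(nbhd[u], nbhd[v], n_avg, params.pseudocount)


def build_fsweight_network(
    direct: nx.Graph, params: FSWeightParams | None = None
) -> nx.Graph:
    """Rescore a correlation network by FS-Weight, adding indirect edges.

    * Direct edges with S >= threshold are kept (``kind="direct"``, original
      attributes preserved, score stored as ``fs_weight``).
    * Non-adjacent pairs sharing at least one neighbor with S >= threshold
      are added (``kind="indirect"``, ``weight`` = S, no sign — only
      correlation edges carry a sign).
    * Direct edges scoring below the threshold are removed.

    The node set of the result is exactly the set of surviving-edge
    endpoints. One pass only; the augmented network is not re-scored.
    """
    params = params or FSWeightParams()
    out = nx.Graph(method="fsweight", fsw_threshold=params.threshold)
    if direct.number_of_nodes() == 0:
        logger.warning("build_fsweight_network: empty input network")
        return out

    nbhd = _neighborhoods(direct, params.include_self)
    n_avg = sum(len(n) for n in nbhd.values()) / len(nbhd)

    candidates = {frozenset(e) for e in direct.edges}
    for v in direct:
        for a, b in combinations(direct[v], 2):
            if a != b:
                candidates.add(frozenset((a, b)))

    for pair in sorted(candidates, key=sorted):
        u, v = sorted(pair)
        s = _score(nbhd[u], nbhd[v], n_avg, params.pseudocount)
        if s < params.threshold:
            continue
        if direct.has_edge(u, v):
            attrs = dict(direct.edges[u, v])
            attrs["kind"] = "direct"
            attrs["fs_weight"] = s
            out.add_edge(u, v, **attrs)
        else:
            out.add_edge(u, v, weight=s, kind="indirect", fs_weight=s)
    return out
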