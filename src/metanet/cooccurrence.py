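"""Co-occurrence probabilities and correlation network construction.

The co-occurrence probability of a taxon pair is the fraction of samples in
which both are present (non-zero abundance). The *strict* network computes a
correlation only for pairs co-present in **every** sample; the *loose*
network relaxes that to a user-set co-occurrence threshold (default 0.8),
recovering pairs that the strict rule discards in sparse data while still
filtering pairs seen together in too few samples to support a correlation.

Networks are :class:`networkx.Graph` objects. Edges carry ``weight`` (the
correlation coefficient), ``sign`` ("positive"/"negative"), ``kind``
("direct" here) and ``p_value``; the graph itself carries ``method`` and the
thresholds used. Only taxa that end up with at least one edge become nodes.
"""

from __future__ import annotations

import logging
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "cooccurrence_probability",
    "build_strict_network",
    "build_loose_network",
]

#: default pairwise-correlation thresholds at the two taxonomic levels
LEVEL_CORR_THRESHOLDS = {"genus": 0.5, "otu": 0.7}


def cooccurrence_probability(pa: pd.DataFrame) -> pd.DataFrame:
    """Taxa-by-taxa matrix of co-occurrence probabilities.

    ``pa`` is a presence/absence matrix (entries in {0, 1}); entry (i, j) of
    the result is |samples where both i and j are 1| / C. The diagonal is
    each taxon's presence fraction, and every off-diagonal entry is bounded
    by the smaller of the two diagonal entries.
    """
    values = pa.to_numpy()
    if values.size == 0 or pa.shape[1] < 1:
        raise ParameterError("presence/absence matrix needs at least one sample")
    uniq = np.unique(values)
    if not np.isin(uniq, (0, 1)).all():
        raise ParameterError("presence/absence matrix must be strictly binary")
    b = values.astype(np.int64)
    counts = b @ b.T
    probs = counts / pa.shape[1]
    return pd.DataFrame(probs, index=pa.index, columns=pa.index)


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value from the standard null."""
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


def _add_corr_edges(
    graph: nx.Graph,
    evaluated: list[tuple[str, str, float, float]],
    corr_threshold: float,
    p_threshold: float,
    fdr_bh: bool,
) -> None:
    if fdr_bh and evaluated:
        pvals = stats.false_discovery_control([e[3] for e in evaluated], method="bh")
        evaluated = [(u, v, r, float(q)) for (u, v, r, _), q in zip(evaluated, pvals)]
    for u, v, r, p in evaluated:
        if abs(r) >= corr_threshold and p <= p_threshold:
            graph.add_edge(
                u,
                v,
                weight=r,
                sign="positive" if r >= 0 else "negative",
                kind="direct",
                p_value=p,
            )


def build_strict_network(
    m: pd.DataFrame,
    corr: str = "pearson",
    corr_threshold: float = 0.5,
    p_threshold: float = 0.01,
    fdr_bh: bool = False,
) -> nx.Graph:
    """Correlation network restricted to pairs with 100% co-occurrence.

    A pair is evaluated only if both taxa are present (abundance > 0) in
    every sample; the correlation then uses all samples. Edges require
    |coefficient| >= ``corr_threshold`` and p <= ``p_threshold``. Pairs with
    a constant abundance vector are skipped with a logged warning.
    """
    if m.shape[1] < 3:
        raise ParameterError("strict network needs at least 3 samples")
    values = m.to_numpy(dtype=float)
    present = values > 0
    n_samples = m.shape[1]
    co_counts = present.astype(np.int64) @ present.astype(np.int64).T
    taxa = list(m.index)

    evaluated: list[tuple[str, str, float, float]] = []
    for i, j in combinations(range(len(taxa)), 2):
        if co_counts[i, j] != n_samples:
            continue
        x, y = values[i], values[j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning(
                "strict network: constant abundance for pair (%s, %s); skipped",
                taxa[i],
                taxa[j],
            )
            continue
        r, p = _corr(x, y, corr)
        evaluated.append((taxa[i], taxa[j], r, p))

    graph = nx.Graph(
        method=corr,
        corr_threshold=corr_threshold,
        p_threshold=p_threshold,
        cooc_threshold=1.0,
    )
    _add_corr_edges(graph, evaluated, corr_threshold, p_threshold, fdr_bh)
    return graph


def build_loose_network(
    m: pd.DataFrame,
    cooc_threshold: float = 0.8,
    corr: str = "pearson",
    corr_threshold: float = 0.5,
    p_threshold: float = 0.01,
    corr_scope: str = "copresent_samples",
    fdr_bh: bool = False,
) -> nx.Graph:
    """Correlation network under the loose co-occurrence definition.

    Exactly the pairs whose co-occurrence probability is >= ``cooc_threshold``
    (boundary included) are evaluated. Under the default
    ``corr_scope="copresent_samples"`` the coefficient uses only samples
    where both taxa are present — joint absences cannot manufacture
    correlation; ``"all_samples"`` uses every sample (and at threshold 1.0
    reproduces :func:`build_strict_network` edge-for-edge). Pairs with fewer
    than 3 co-present samples are skipped with a warning: a correlation
    supported by a couple of samples is noise, however large it looks.
    """
    if not 0.0 <= cooc_threshold <= 1.0:
        raise ParameterError(f"cooc_threshold must be in [0, 1], got {cooc_threshold}")
    if corr_scope not in ("copresent_samples", "all_samples"):
        raise ParameterError(f"unknown corr_scope {corr_scope!r}")
    if m.shape[1] < 3:
        raise ParameterError("loose network needs at least 3 samples")
    values = m.to_numpy(dtype=float)
    present = values > 0
    n_samples = m.shape[1]
    co_counts = present.astype(np.int64) @ present.astype(np.int64).T
    taxa = list(m.index)

    evaluated: list[tuple[str, str, float, float]] = []
    for i, j in combinations(range(len(taxa)), 2):
        if co_counts[i, j] / n_samples < cooc_threshold:
            continue
        if corr_scope == "copresent_samples":
            mask = present[i] & present[j]
            if mask.sum() < 3:
                logger.warning(
                    "loose network: pair (%s, %s) has only %d co-present samples; skipped",
                    taxa[i],
                    taxa[j],
                    int(mask.sum()),
                )
                continue
            x, y = values[i, mask], values[j, mask]
        else:
            x, y = values[i], values[j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning(
                "loose network: constant abundance for pair (%s, %s); skipped",
                taxa[i],
                taxa[j],
            )
            continue
        r, p = _corr(x, y, corr)
        evaluated.append((taxa[i], taxa[j], r, p))

    graph = nx.Graph(
        method="loose",
        corr=corr,
        corr_threshold=corr_threshold,
        p_threshold=p_threshold,
        cooc_threshold=cooc_threshold,
        corr_scope=corr_scope,
    )
    _add_corr_edges(graph, evaluated, corr_threshold, p_threshold, fdr_bh)
    return graph
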