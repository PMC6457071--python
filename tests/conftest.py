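import networkx as nx
import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def small_abundance() -> pd.DataFrame:
    """3 taxa x 4 samples, relative abundances, no zeros."""
    return pd.DataFrame(
        [[0.5, 0.4, 0.6, 0.3], [0.3, 0.35, 0.25, 0.45], [0.2, 0.25, 0.15, 0.25]],
        index=["Bacteroides", "Prevotella", "Ruminococcus"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def bridged_cliques() -> nx.Graph:
    """Two 5-cliques joined by a single bridge edge A4-B4."""
    g = nx.Graph()
    for pre in ("A", "B"):
        nodes = [f"{pre}{i}" for i in range(5)]
        g.add_edges_from((u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:])
    g.add_edge("A4", "B4")
    return g


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g})


def random_abundance(n_taxa: int, n_samples: int, seed: int, zero_frac: float = 0.0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=0.0, sigma=1.0, size=(n_taxa, n_samples))
    if zero_frac:
        values[rng.random(values.shape) < zero_frac] = 0.0
    values /= np.where(values.sum(0) > 0, values.sum(0), 1.0)
    return pd.DataFrame(
        values,
        index=[f"T{i:02d}" for i in range(n_taxa)],
        columns=[f"S{j:02d}" for j in range(n_samples)],
    )
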