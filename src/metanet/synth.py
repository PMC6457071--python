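"""Synthetic microbial communities with planted dependency structure.

The generator emulates what an amplicon pipeline hands to network
inference: a sparse, zero-inflated relative-abundance table with a few
dominant taxa, in which some taxon pairs are coupled directly (linear on
the log scale), some through a shared intermediate (chains x -> z -> y with
x independent of y given z), and some nonlinearly. Alongside the table it
returns the ground-truth interaction network, so every inference stage can
be scored without external data.

Model: each taxon has a log-scale baseline mu_i + standard normal noise;
a planted dependency replaces the target's row with, writing x~ for the
parent's centred signal standardised by its analytic variance,

    linear      y = mu_y + s * x~ + sigma * eps
    quadratic   y = mu_y + s * (x~^2 - 1) / sqrt(2) + sigma * eps
    sinusoidal  y = mu_y + s * sqrt(2) * sin(x~) + sigma * eps

on the log scale (standardising keeps log-variance near 1 at any
dependency depth). The field is scaled by ``log_sigma``, exponentiated,
zeroed independently with probability ``dropout`` (detection-limit zeros
are applied after dependency generation so sparsity attenuates but does
not redefine planted structure), and the columns are closed to relative
abundance.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "CommunitySpec",
    "generate_community",
    "random_spec",
    "ground_truth_metrics",
]

#: log-scale baseline gap between dominant and rare taxa; e^-7 keeps rare
#: taxa safely below 0.1% mean relative abundance at realistic richness
_RARE_MU = -7.0

_FORMS = ("linear", "quadratic", "sinusoidal")


@dataclass(frozen=True)
class CommunitySpec:
    """Recipe for a synthetic community.

    direct_edges are ``(source, target, strength)`` with strength in (0, 1];
    chains are ``(x, z, y)`` triples realised as x -> z -> y with no direct
    x-y coupling; nonlinear_edges are ``(source, target, form)`` with form
    "quadratic" or "sinusoidal". Chain triples must be node-disjoint from
    every other planted element (that is what guarantees x independent of y
    given z); any other target may have several parents, but the direct-edge
    graph must be acyclic. ``n_dominant`` taxa (the first ones) get the high
    baseline; None means all.
    """

    n_taxa: int
    n_samples: int
    direct_edges: tuple = ()
    chains: tuple = ()
    nonlinear_edges: tuple = ()
    dropout: float = 0.0
    n_dominant: int | None = None
    seed: int = 0
    noise_sigma: float = 0.75
    chain_strength: float = 0.8
    log_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_samples < 2:
            raise ParameterError("need at least 2 taxa and 2 samples")
        if not 0.0 <= self.dropout < 1.0:
            raise ParameterError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.log_sigma <= 0:
            raise ParameterError("log_sigma must be > 0")
        if self.n_dominant is not None and not 0 <= self.n_dominant <= self.n_taxa:
            raise ParameterError(f"n_dominant must be in [0, {self.n_taxa}]")
        self._validate_structure()

    def _validate_structure(self) -> None:
        def check_index(i) -> None:
            if not 0 <= i < self.n_taxa:
                raise ParameterError(f"taxon index {i} out of range [0, {self.n_taxa})")

        chain_sets: list[set[int]] = []
        chain_nodes: set[int] = set()
        for x, z, y in self.chains:
            for i in (x, z, y):
                check_index(i)
            if len({x, z, y}) != 3:
                raise ParameterError(f"degenerate chain {(x, z, y)}")
            if chain_nodes & {x, z, y}:
                raise ParameterError("chains must be node-disjoint from each other")
            chain_nodes |= {x, z, y}
            chain_sets.append({x, z, y})

        seen_edges: set[frozenset] = set()
        direct_pairs = []

        def check_pair(i, j) -> None:
            check_index(i)
            check_index(j)
            if i == j:
                raise ParameterError(f"self-edge {(i, j)}")
            if any(i in cs and j in cs for cs in chain_sets):
                # an extra edge inside a triple would break x _||_ y | z
                raise ParameterError(f"edge {(i, j)} connects members of one chain")
            key = frozenset((i, j))
            if key in seen_edges:
                raise ParameterError(f"duplicate planted edge {(i, j)}")
            seen_edges.add(key)
            direct_pairs.append((i, j))

        for i, j, s in self.direct_edges:
            if not isinstance(s, (int, float)) or not 0 < s <= 1:
                raise ParameterError(f"invalid direct edge {(i, j, s)}")
            check_pair(i, j)
        for i, j, form in self.nonlinear_edges:
            if form not in ("quadratic", "sinusoidal"):
                raise ParameterError(f"invalid nonlinear edge {(i, j, form)}")
            check_pair(i, j)

        # parent graph must be acyclic so generation has a topological order
        dag = nx.DiGraph()
        dag.add_nodes_from(range(self.n_taxa))
        dag.add_edges_from(direct_pairs)
        for x, z, y in self.chains:
            dag.add_edge(x, z)
            dag.add_edge(z, y)
        if not nx.is_directed_acyclic_graph(dag):
            raise ParameterError("planted dependencies contain a directed cycle")


def _parent_map(spec: CommunitySpec) -> dict[int, list[tuple[int, float, str]]]:
    parents: dict[int, list[tuple[int, float, str]]] = {}
    for i, j, s in spec.direct_edges:
        parents.setdefault(j, []).append((i, s, "linear"))
    for x, z, y in spec.chains:
        parents.setdefault(z, []).append((x, spec.chain_strength, "linear"))
        parents.setdefault(y, []).append((z, spec.chain_strength, "linear"))
    for i, j, form in spec.nonlinear_edges:
        parents.setdefault(j, []).append((i, spec.chain_strength, form))
    return parents


def _contribution(form: str, x: np.ndarray, strength: float) -> np.ndarray:
    if form == "linear":
        return strength * x
    if form == "quadratic":
        return strength * (x**2 - 1.0) / math.sqrt(2.0)
    return strength * math.sqrt(2.0) * np.sin(x)


def generate_community(spec: CommunitySpec) -> tuple[pd.DataFrame, nx.Graph]:
    """Generate an abundance table and its ground-truth network.

    Returns ``(abundance, truth)``: a taxa-by-samples relative-abundance
    DataFrame (columns closed to 1, up to all-zero columns) and an
    undirected graph whose edges are the planted dependencies, each tagged
    with ``kind`` ("direct", "chain", "nonlinear"), ``strength`` and
    ``form``. Bit-identical for a fixed spec (single seeded generator).
    """
    rng = np.random.default_rng(spec.seed)
    r, c = spec.n_taxa, spec.n_samples
    n_dom = spec.n_dominant if spec.n_dominant is not None else r
    mu = np.full(r, 0.0)
    mu[n_dom:] = _RARE_MU

    log_ab = mu[:, None] + rng.standard_normal((r, c))
    parents = _parent_map(spec)

    dag = nx.DiGraph()
    dag.add_nodes_from(range(r))
    for j, ps in parents.items():
        for i, _, _ in ps:
            dag.add_edge(i, j)
    # Parent signals are standardised (analytic variance) before coupling, so
    # log-variance stays near 1 at any dependency depth instead of
    # accumulating along chains and drowning the rest of the community.
    log_var = np.ones(r)
    for t in nx.lexicographical_topological_sort(dag):
        if t not in parents:
            continue
        row = mu[t] + spec.noise_sigma * rng.standard_normal(c)
        for src, strength, form in parents[t]:
            standardized = (log_ab[src] - mu[src]) / math.sqrt(log_var[src])
            row = row + _contribution(form, standardized, strength)
        log_ab[t] = row
        log_var[t] = spec.noise_sigma**2 + sum(s**2 for _, s, _ in parents[t])

    # overall log-scale dispersion: correlations are invariant to this
    # factor, but closure noise in the relative abundances is not — wide
    # per-taxon dispersion lets a few samples' dominant taxa drive the
    # sample total and bleed spurious correlation into every pair
    abundance = np.exp(mu[:, None] + spec.log_sigma * (log_ab - mu[:, None]))
    if spec.dropout > 0:
        abundance[rng.random((r, c)) < spec.dropout] = 0.0
    sums = abundance.sum(axis=0)
    abundance = abundance / np.where(sums > 0, sums, 1.0)

    taxa = [f"T{i:03d}" for i in range(r)]
    samples = [f"S{j:03d}" for j in range(c)]
    df = pd.DataFrame(abundance, index=taxa, columns=samples)

    truth = nx.Graph(method="truth")
    truth.add_nodes_from(taxa)
    for i, j, s in spec.direct_edges:
        truth.add_edge(taxa[i], taxa[j], kind="direct", strength=s, form="linear")
    for x, z, y in spec.chains:
        truth.add_edge(taxa[x], taxa[z], kind="chain", strength=spec.chain_strength, form="linear")
        truth.add_edge(taxa[z], taxa[y], kind="chain", strength=spec.chain_strength, form="linear")
    for i, j, form in spec.nonlinear_edges:
        truth.add_edge(taxa[i], taxa[j], kind="nonlinear", strength=spec.chain_strength, form=form)
    return df, truth


def random_spec(
    n_taxa: int,
    n_samples: int,
    n_direct: int = 0,
    n_chains: int = 0,
    n_nonlinear: int = 0,
    dropout: float = 0.0,
    n_dominant: int | None = None,
    seed: int = 0,
    strength: float = 0.8,
    noise_sigma: float = 0.75,
) -> CommunitySpec:
    """Draw a random planted structure of the requested size.

    Chain triples take node-disjoint taxa; nonlinear edges (alternating
    quadratic/sinusoidal) take further fresh taxa; direct edges form a
    random DAG over the remaining pool (targets may repeat, so more edges
    than pool nodes are possible).
    """
    rng = np.random.default_rng(seed)
    need = 3 * n_chains + 2 * n_nonlinear
    if need > n_taxa:
        raise ParameterError("not enough taxa for the requested planted structure")
    perm = [int(v) for v in rng.permutation(n_taxa)]
    chains = tuple(
        (perm[3 * k], perm[3 * k + 1], perm[3 * k + 2]) for k in range(n_chains)
    )
    chain_sets = [set(c) for c in chains]
    base = 3 * n_chains
    nonlinear = tuple(
        (perm[base + 2 * k], perm[base + 2 * k + 1], _FORMS[1 + k % 2])
        for k in range(n_nonlinear)
    )
    # Direct edges live on the taxa not used by chains or nonlinear pairs
    # (the permutation is the topological order), placed round-robin over
    # targets with at most 2 parents and 2 children per node: a target with
    # k parents shares its variance k ways, and a source with many children
    # spawns a near-collinear sibling block; either way the planted
    # per-edge signal is diluted relative to induced correlations. Two
    # targets never share an identical parent pair — such twins would be
    # statistical near-duplicates and explain each other's edges away.
    pool = perm[base + 2 * n_nonlinear :]
    if n_direct > 0 and len(pool) < 2:
        raise ParameterError("not enough taxa for the requested planted structure")
    edges: list[tuple[int, int, float]] = []
    seen: set[frozenset] = set()
    in_deg = {v: 0 for v in pool}
    out_deg = {v: 0 for v in pool}
    parent_sets: dict[int, set[int]] = {}
    used_pairs: set[frozenset] = set()
    for _pass in range(2):
        for t_pos in range(1, len(pool)):
            if len(edges) >= n_direct:
                break
            t = pool[t_pos]
            if in_deg[t] >= 2:
                continue
            current = parent_sets.get(t, set())
            choices = [
                s
                for s in pool[:t_pos]
                if out_deg[s] < 2
                and frozenset((s, t)) not in seen
                and (not current or frozenset(current | {s}) not in used_pairs)
            ]
            if not choices:
                continue
            s = choices[int(rng.integers(0, len(choices)))]
            seen.add(frozenset((s, t)))
            out_deg[s] += 1
            in_deg[t] += 1
            parent_sets[t] = current | {s}
            if len(parent_sets[t]) == 2:
                used_pairs.add(frozenset(parent_sets[t]))
            edges.append((s, t, strength))
    if len(edges) < n_direct:
        raise ParameterError("could not place the requested number of direct edges")
    return CommunitySpec(
        n_taxa=n_taxa,
        n_samples=n_samples,
        direct_edges=tuple(edges),
        chains=chains,
        nonlinear_edges=nonlinear,
        dropout=dropout,
        n_dominant=n_dominant,
        seed=seed,
        noise_sigma=noise_sigma,
        chain_strength=strength,
    )


def ground_truth_metrics(inferred: nx.Graph, truth: nx.Graph) -> tuple[float, float, float]:
    """Edge-set precision, recall and F1 of ``inferred`` against ``truth``.

    An empty inferred edge set has precision 1 by convention (nothing wrong
    was claimed) with a warning; an empty truth edge set has recall 1.
    """
    inferred_edges = {frozenset(e) for e in inferred.edges}
    truth_edges = {frozenset(e) for e in truth.edges}
    tp = len(inferred_edges & truth_edges)
    if inferred_edges:
        precision = tp / len(inferred_edges)
    else:
        warnings.warn("inferred network has no edges; precision defined as 1.0", stacklevel=2)
        precision = 1.0
    recall = tp / len(truth_edges) if truth_edges else 1.0
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1
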