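"""Part mutual information (PMI) with path-consistency pruning.

Pearson/Spearman networks miss nonlinear dependence, and raw mutual
information cannot separate a direct dependency from one routed through a
shared neighbor. PMI addresses the latter: for abundance variables x, y and
a conditioning vector z,

    PMI(x, y | z) = sum_{x,y,z} p(x,y,z) * log[ p(x,y|z) / (p*(x|z) p*(y|z)) ]

with the partially marginalised conditionals

    p*(y|z) = sum_x p(y|z,x) p(x)        p*(x|z) = sum_y p(x|z,y) p(y).

With an empty conditioning set PMI reduces exactly to mutual information.

The path-consistency loop builds an order-0 network from pairwise dependence
and then, at increasing conditioning order L, removes an edge whenever some
size-L subset of the pair's current common neighbors drops its PMI to or
below the threshold (that subset is the pair's separating set). Orders
increase until an order changes nothing.

Two estimators are provided:

* ``"gaussian"`` (default) — closed form -0.5*log(1 - rho^2) on the
  (partial) correlation. Inside :func:`pca_pmi_network` the abundances are
  first prepared for compositional, zero-inflated data: log-transformed,
  centred by each sample's median log-abundance (a robust correction for
  closure — dividing by the sample total couples every pair through the
  total's fluctuations), mapped to per-taxon rank normal scores, with zeros
  treated as missing (detection-limit dropout carries no rank information,
  and treating it as a tied value dilutes every correlation); correlations
  then use pairwise/conditionally complete samples.
* ``"binned"`` — equal-frequency discretisation followed by the literal
  discrete sums above; exact for discrete distributions and invariant under
  strictly monotone transforms, but biased upward on continuous data at
  realistic sample sizes, so the default edge threshold is calibrated for
  the Gaussian form.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import stats
from scipy.special import ndtri

from .errors import AbundanceError, EstimationWarning, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "PmiParams",
    "mutual_information",
    "part_mutual_information",
    "pmi_from_joint",
    "pca_pmi_network",
]


@dataclass
class PmiParams:
    """Parameters for PMI estimation and path-consistency pruning.

    threshold
        Edge-retention threshold on the dependence statistic (nats),
        default 0.02. An edge exists when the statistic is strictly
        greater; it is removed when some conditioning subset drops the PMI
        to <= threshold.
    estimator
        "gaussian" (closed form, default) or "binned" (equal-frequency
        discretisation, literal discrete sums).
    n_bins
        Bins per variable for the binned estimator; None means
        ceil(sqrt(n_samples)).
    max_order
        Highest conditioning order tried; None iterates until no order
        changes any edge.
    """

    threshold: float = 0.02
    estimator: str = "gaussian"
    n_bins: int | None = None
    max_order: int | None = 3

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ParameterError(f"threshold must be > 0, got {self.threshold}")
        if self.estimator not in ("binned", "gaussian"):
            raise ParameterError(f"unknown estimator {self.estimator!r}")
        if self.n_bins is not None and self.n_bins < 2:
            raise ParameterError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.max_order is not None and self.max_order < 0:
            raise ParameterError(f"max_order must be >= 0, got {self.max_order}")

    def resolve_bins(self, n_samples: int) -> int:
        return self.n_bins if self.n_bins is not None else max(2, math.ceil(math.sqrt(n_samples)))


# ---------------------------------------------------------------------------
# discretisation and discrete cores


def _bin_codes(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin indices from average ranks.

    Tied values share an average rank and therefore always land in the same
    bin (heavy ties, e.g. zero inflation, collapse into one bin rather than
    being smeared into artificial structure). Strictly monotone transforms
    leave ranks, hence codes, unchanged.
    """
    ranks = stats.rankdata(x, method="average")
    codes = np.floor((ranks - 0.5) * n_bins / len(x)).astype(np.int64)
    return np.clip(codes, 0, n_bins - 1)


def pmi_from_joint(p: np.ndarray) -> float:
    """PMI of a discrete joint distribution ``p[x, y, z]`` (z may be flattened).

    Implements the partially marginalised conditionals directly on the
    probability table; the result is clamped at 0. With a trivial z axis
    (size 1) this is exactly the mutual information of (x, y).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 3:
        raise ParameterError(f"joint distribution must be 3-dimensional, got ndim={p.ndim}")
    if (p < 0).any():
        raise ParameterError("joint distribution has negative entries")
    total = p.sum()
    if abs(total - 1.0) > 1e-9:
        raise ParameterError(f"joint distribution must sum to 1 (got {total!r})")

    px = p.sum(axis=(1, 2))
    py = p.sum(axis=(0, 2))
    pz = p.sum(axis=(0, 1))
    pxz = p.sum(axis=1)  # (x, z)
    pyz = p.sum(axis=0)  # (y, z)

    with np.errstate(divide="ignore", invalid="ignore"):
        # p*(y|z) = sum_x p(y|z,x) p(x), with p(y|z,x) = p(x,y,z)/p(x,z)
        ratio_x = np.where(pxz > 0, 1.0 / pxz, 0.0)  # (x, z)
        p_star_yz = np.einsum("xyz,xz,x->yz", p, ratio_x, px)
        ratio_y = np.where(pyz > 0, 1.0 / pyz, 0.0)  # (y, z)
        p_star_xz = np.einsum("xyz,yz,y->xz", p, ratio_y, py)

    value = 0.0
    xs, ys, zs = np.nonzero(p)
    for xi, yi, zi in zip(xs, ys, zs):
        p_xy_given_z = p[xi, yi, zi] / pz[zi]
        denom = p_star_xz[xi, zi] * p_star_yz[yi, zi]
        if denom <= 0:
            continue
        value += p[xi, yi, zi] * math.log(p_xy_given_z / denom)
    return max(value, 0.0)


def _mi_from_codes(cx: np.ndarray, cy: np.ndarray, n_bins: int) -> float:
    n = len(cx)
    joint = np.bincount(cx * n_bins + cy, minlength=n_bins * n_bins).reshape(n_bins, n_bins)
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mask = p > 0
    outer = np.outer(px, py)
    value = float(np.sum(p[mask] * np.log(p[mask] / outer[mask])))
    return max(value, 0.0)


def _gaussian_mi_from_r(r: float) -> float:
    r2 = min(r * r, 1.0 - 1e-15)
    return -0.5 * math.log1p(-r2)


def _partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray | None) -> float:
    """Pearson correlation of x and y after regressing out the rows of z."""
    if z is not None and z.size:
        design = np.column_stack([np.ones(len(x)), z.T])
        bx, *_ = np.linalg.lstsq(design, x, rcond=None)
        by, *_ = np.linalg.lstsq(design, y, rcond=None)
        x = x - design @ bx
        y = y - design @ by
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.dot(x - x.mean(), y - y.mean()) / (len(x) * sx * sy))
    return float(np.clip(r, -1.0, 1.0))


# ---------------------------------------------------------------------------
# public estimators


def _check_vectors(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ParameterError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ParameterError("need vectors of length >= 3")
    return x, y


def mutual_information(x, y, params: PmiParams | None = None) -> float:
    """Mutual information of two abundance vectors (nats, >= 0).

    Binned: equal-frequency discretisation into ``n_bins`` bins followed by
    the plug-in sum. Gaussian: -0.5*log(1 - r^2) with r the Pearson
    coefficient. A constant vector has MI 0 by convention.
    """
    params = params or PmiParams()
    x, y = _check_vectors(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    if params.estimator == "gaussian":
        r = float(np.corrcoef(x, y)[0, 1])
        return _gaussian_mi_from_r(r)
    n_bins = params.resolve_bins(len(x))
    return _mi_from_codes(_bin_codes(x, n_bins), _bin_codes(y, n_bins), n_bins)


def part_mutual_information(
    x, y, z=None, params: PmiParams | None = None
) -> float:
    """PMI of x and y given the conditioning rows of ``z`` (nats, >= 0).

    ``z`` is a (k, n) matrix of conditioning vectors (or None/empty, in which
    case the value equals :func:`mutual_information`). The binned estimator
    emits an :class:`EstimationWarning` when fewer than half of the joint
    bins are occupied — the estimate is then low-confidence.
    """
    params = params or PmiParams()
    x, y = _check_vectors(x, y)
    if z is not None:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.size == 0:
            z = None
        elif z.shape[1] != len(x):
            raise ParameterError(f"conditioning length mismatch: {z.shape[1]} vs {len(x)}")

    if params.estimator == "gaussian":
        rho = _partial_corr(x, y, z)
        return _gaussian_mi_from_r(rho)

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    n_bins = params.resolve_bins(len(x))
    cx = _bin_codes(x, n_bins)
    cy = _bin_codes(y, n_bins)
    if z is None:
        cz = np.zeros(len(x), dtype=np.int64)
        nz = 1
    else:
        z_codes = [_bin_codes(row, n_bins) for row in z]
        flat = np.ravel_multi_index(z_codes, dims=[n_bins] * len(z_codes))
        _, cz = np.unique(flat, return_inverse=True)
        nz = int(cz.max()) + 1
    joint = np.zeros((n_bins, n_bins, nz))
    np.add.at(joint, (cx, cy, cz), 1.0)
    joint /= len(x)
    occupancy = np.count_nonzero(joint) / joint.size
    if z is not None and occupancy < 0.5:
        warnings.warn(
            f"PMI joint support only {occupancy:.0%} occupied; estimate is low-confidence",
            EstimationWarning,
            stacklevel=2,
        )
    return pmi_from_joint(joint)


# ---------------------------------------------------------------------------
# network inference


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Row-wise rank normal scores (van der Waerden); constant rows -> 0."""
    out = np.zeros_like(values, dtype=float)
    n = values.shape[1]
    for i, row in enumerate(values):
        if np.ptp(row) == 0:
            continue
        out[i] = ndtri(stats.rankdata(row, method="average") / (n + 1))
    return out


#: minimum complete samples for a (partial) correlation to be trusted
_MIN_COMPLETE = 8


def _prepare_scores(values: np.ndarray) -> np.ndarray:
    """Compositional-aware score matrix for the Gaussian estimator.

    Log of positive entries, centred per sample by the median log-abundance
    of the detected taxa, then per-taxon rank normal scores of the observed
    entries; zeros become NaN (missing).
    """
    with np.errstate(divide="ignore"):
        logv = np.where(values > 0, np.log(np.where(values > 0, values, 1.0)), np.nan)
    med = np.nanmedian(logv, axis=0)
    centred = logv - med
    out = np.full(values.shape, np.nan)
    for i, row in enumerate(centred):
        obs = np.isfinite(row)
        n_obs = int(obs.sum())
        if n_obs >= 3 and np.ptp(row[obs]) > 0:
            out[i, obs] = ndtri(stats.rankdata(row[obs], method="average") / (n_obs + 1))
    return out


def _masked_partial_corr(x: np.ndarray, y: np.ndarray, z_rows: np.ndarray | None) -> float:
    """Partial correlation over the samples where x, y and all conditioning
    rows are observed; 0 when too few complete samples remain."""
    mask = np.isfinite(x) & np.isfinite(y)
    if z_rows is not None:
        for row in z_rows:
            mask &= np.isfinite(row)
    n_z = 0 if z_rows is None else len(z_rows)
    if int(mask.sum()) < max(_MIN_COMPLETE, n_z + 3):
        return 0.0
    x, y = x[mask], y[mask]
    z = None if z_rows is None else z_rows[:, mask]
    return _partial_corr(x, y, z)


def pca_pmi_network(m, params: PmiParams | None = None) -> nx.Graph:
    """Infer a dependence network by path-consistency-pruned PMI.

    Order 0 connects every taxon pair whose pairwise dependence statistic
    exceeds the threshold. At order L >= 1, each surviving edge (i, j) is
    tested against every size-L subset of its current common neighbors; if
    any subset drops the PMI to <= threshold the edge is removed and that
    subset recorded as the separating set. Orders increase until one changes
    no edges (or ``max_order`` is reached). Surviving edges carry
    ``weight`` = the minimum statistic observed across all tests.

    Removals are logged and collected in ``G.graph["removals"]`` as
    ``(u, v, order, separating_set)`` tuples.
    """
    params = params or PmiParams()
    values = m.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise AbundanceError("abundance matrix contains non-finite values")
    n_taxa, n_samples = values.shape
    if n_samples < 3:
        raise ParameterError("PCA-PMI needs at least 3 samples")
    taxa = list(m.index)

    if params.estimator == "gaussian":
        scores = _prepare_scores(values)
        rmat = np.zeros((n_taxa, n_taxa))
        for i, j in combinations(range(n_taxa), 2):
            rmat[i, j] = rmat[j, i] = _masked_partial_corr(scores[i], scores[j], None)

        def stat0(i: int, j: int) -> float:
            return _gaussian_mi_from_r(rmat[i, j])

        def stat_cond(i: int, j: int, subset: tuple[int, ...]) -> float:
            rho = _masked_partial_corr(scores[i], scores[j], scores[list(subset)])
            return _gaussian_mi_from_r(rho)

    else:
        n_bins = params.resolve_bins(n_samples)
        codes = np.stack([_bin_codes(row, n_bins) for row in values])
        consts = np.array([np.ptp(row) == 0 for row in values])

        def stat0(i: int, j: int) -> float:
            if consts[i] or consts[j]:
                return 0.0
            return _mi_from_codes(codes[i], codes[j], n_bins)

        def stat_cond(i: int, j: int, subset: tuple[int, ...]) -> float:
            if consts[i] or consts[j]:
                return 0.0
            flat = np.ravel_multi_index(
                [codes[k] for k in subset], dims=[n_bins] * len(subset)
            )
            _, cz = np.unique(flat, return_inverse=True)
            nz = int(cz.max()) + 1
            joint = np.zeros((n_bins, n_bins, nz))
            np.add.at(joint, (codes[i], codes[j], cz), 1.0)
            joint /= n_samples
            return pmi_from_joint(joint)

    graph = nx.Graph(
        method="pcapmi",
        pmi_threshold=params.threshold,
        estimator=params.estimator,
    )
    graph.graph["removals"] = []
    min_stat: dict[frozenset, float] = {}
    for i, j in combinations(range(n_taxa), 2):
        s = stat0(i, j)
        if s > params.threshold:
            graph.add_edge(taxa[i], taxa[j], weight=s, kind="direct")
            if params.estimator == "gaussian":
                graph.edges[taxa[i], taxa[j]]["sign"] = (
                    "positive" if rmat[i, j] >= 0 else "negative"
                )
            min_stat[frozenset((i, j))] = s

    index = {t: k for k, t in enumerate(taxa)}
    order = 1
    while params.max_order is None or order <= params.max_order:
        changed = False
        # adjacency snapshot per order (PC-stable): the separating-set
        # search is then independent of the edge visiting order within an
        # order, and a separator cannot vanish before the pair it separates
        # is tested
        snapshot = {v: set(graph[v]) for v in graph}
        for u, v in sorted(graph.edges):
            common = sorted(snapshot[u] & snapshot[v])
            if len(common) < order:
                continue
            i, j = index[u], index[v]
            key = frozenset((i, j))
            for subset in combinations(common, order):
                s = stat_cond(i, j, tuple(index[w] for w in subset))
                min_stat[key] = min(min_stat[key], s)
                if s <= params.threshold:
                    graph.remove_edge(u, v)
                    graph.graph["removals"].append((u, v, order, subset))
                    logger.info(
                        "pcapmi: removed edge (%s, %s) at order %d; separating set %s "
                        "(PMI %.4g <= %.4g)",
                        u, v, order, subset, s, params.threshold,
                    )
                    changed = True
                    break
            else:
                graph.edges[u, v]["weight"] = min_stat[key]
        if not changed:
            break
        order += 1

    graph.remove_nodes_from([v for v in list(graph) if graph.degree(v) == 0])
    return graph
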