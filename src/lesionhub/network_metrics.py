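"""Binary functional-network construction and graph-topological measures.

A subject's functional connectome enters as a symmetric Fisher-z
connectivity matrix.  Only positive weights are meaningful as edges:
binarisation keeps the strongest positive connections up to a target
*sparsity* (fraction of all possible edges).  On the binary graph the
module computes global efficiency (integration), local efficiency
(segregation), their nodal variant, and the small-world index sigma —
the ratio of local to global efficiency after each is scaled by its mean
over degree-matched rewired null networks.  Metrics can be summarised
across a sparsity grid by the area under the metric curve (AUC), which
removes the arbitrariness of a single threshold.

Efficiency conventions are the standard binary Latora–Marchiori ones:
unreachable pairs contribute zero, and neighbourhood subgraphs with
fewer than two nodes have local efficiency zero.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConfigError, DataError
from ._rng import as_rng, sub_seed

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-8

__all__ = [
    "ConnectivityMatrix",
    "BinaryNetwork",
    "TopologyMetrics",
    "MetricCurve",
    "fisher_z",
    "threshold_by_sparsity",
    "sparsity_range",
    "global_efficiency",
    "local_efficiency",
    "nodal_global_efficiency",
    "degree_matched_randomize",
    "small_world_sigma",
    "auc_over_sparsity",
    "metric_curve",
]


def _default_node_ids(n: int) -> tuple:
    width = max(3, len(str(n - 1)))
    return tuple(f"n{i:0{width}d}" for i in range(n))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric node x node Fisher-z connectivity for one subject.

    The diagonal is forced to zero and the matrix is symmetrised exactly
    (small numerical asymmetry up to 1e-8 is averaged away; anything
    larger is rejected as a data error).
    """

    node_ids: tuple
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DataError(f"connectivity matrix must be square, got shape {w.shape}")
        ids = tuple(str(i) for i in self.node_ids)
        if len(ids) != w.shape[0]:
            raise DataError(
                f"{len(ids)} node ids for a {w.shape[0]}x{w.shape[0]} matrix"
            )
        if len(set(ids)) != len(ids):
            raise DataError("duplicate node ids")
        if not np.all(np.isfinite(w)):
            i, j = np.argwhere(~np.isfinite(w))[0]
            raise DataError(f"non-finite weight at ({ids[i]}, {ids[j]})")
        asym = np.abs(w - w.T).max() if w.size else 0.0
        if asym > _SYMMETRY_TOL:
            raise DataError(f"matrix asymmetry {asym:.3g} exceeds tolerance {_SYMMETRY_TOL}")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "node_ids", ids)
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.node_ids)


@dataclass(frozen=True)
class BinaryNetwork:
    """Unweighted undirected graph obtained by sparsity thresholding.

    ``sparsity`` records the *achieved* fraction of retained edges,
    which can fall below the requested one when too few positive
    weights exist.
    """

    node_ids: tuple
    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DataError(f"adjacency must be square, got shape {a.shape}")
        ids = tuple(str(i) for i in self.node_ids)
        if len(ids) != a.shape[0]:
            raise DataError("node id count does not match adjacency size")
        if np.any(np.diagonal(a)):
            raise DataError("self-edges are not allowed")
        if not np.array_equal(a, a.T):
            raise DataError("adjacency must be symmetric")
        a = a.copy()
        a.flags.writeable = False
        object.__setattr__(self, "node_ids", ids)
        object.__setattr__(self, "adjacency", a)

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass(frozen=True)
class TopologyMetrics:
    """Network-level topology at one sparsity.

    ``scaled_ge`` / ``scaled_loce`` divide the raw efficiency by its
    mean over ``n_random`` degree-matched rewired nulls; ``sigma`` is
    ``scaled_loce / scaled_ge``.
    """

    sparsity: float
    net_ge: float
    net_loce: float
    scaled_ge: float | None = None
    scaled_loce: float | None = None
    sigma: float | None = None
    n_random: int = 0


@dataclass(frozen=True)
class MetricCurve:
    """One network metric evaluated on an ascending sparsity grid."""

    sparsities: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.sparsities, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if s.ndim != 1 or v.ndim != 1 or len(s) != len(v):
            raise DataError("sparsities and values must be 1-D and equally long")
        if len(s) >= 2 and np.any(np.diff(s) <= 0):
            raise DataError("sparsity grid must be strictly ascending")
        object.__setattr__(self, "sparsities", s)
        object.__setattr__(self, "values", v)

    @property
    def auc(self) -> float:
        return auc_over_sparsity(self)


# ---------------------------------------------------------------------------
# construction


def fisher_z(r_matrix, node_ids=None) -> ConnectivityMatrix:
    """Fisher r-to-z transform of a correlation matrix.

    Off-diagonal entries must lie strictly inside (-1, 1); the diagonal
    is discarded (set to zero).  Negative correlations are retained
    here and only dropped at thresholding.
    """
    r = np.asarray(r_matrix, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise DataError(f"correlation matrix must be square, got shape {r.shape}")
    n = r.shape[0]
    ids = tuple(str(i) for i in node_ids) if node_ids is not None else _default_node_ids(n)
    off = ~np.eye(n, dtype=bool)
    bad = off & (np.abs(r) >= 1.0)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"|r| >= 1 between nodes ({ids[i]}, {ids[j]}): r = {r[i, j]:g}"
        )
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    return ConnectivityMatrix(ids, z)


def _ranked_positive_edges(weights: np.ndarray):
    """Upper-triangle positive edges in deterministic rank order.

    Sorted by weight descending; ties broken by lexicographic (i, j),
    so the retained edge set is reproducible across platforms and the
    edge set at a lower sparsity is always a subset of the set at a
    higher one.
    """
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    order = np.lexsort((ju, iu, -w))
    order = order[w[order] > 0]
    return iu[order], ju[order]


def threshold_by_sparsity(cm: ConnectivityMatrix, s: float) -> BinaryNetwork:
    """Binarise by keeping the top ``round(s * n(n-1)/2)`` positive weights.

    If fewer positive weights exist than requested, all of them are
    kept and the achieved sparsity recorded on the result.
    """
    if not 0 < s <= 1:
        raise ConfigError(f"sparsity must lie in (0, 1], got {s}")
    n = cm.n
    if n < 2:
        raise DataError("need at least 2 nodes to threshold")
    m_total = n * (n - 1) // 2
    target = int(round(s * m_total))
    ei, ej = _ranked_positive_edges(cm.weights)
    keep = min(target, len(ei))
    adj = np.zeros((n, n), dtype=bool)
    adj[ei[:keep], ej[:keep]] = True
    adj |= adj.T
    return BinaryNetwork(cm.node_ids, adj, keep / m_total)


def _is_connected(adj: np.ndarray) -> bool:
    if adj.shape[0] < 2:
        return True
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return n_comp == 1


def _min_connected_edge_count(ei, ej, n: int) -> int:
    """Smallest prefix length of the ranked edge list giving a connected graph."""
    lo, hi = n - 1, len(ei)

    def ok(k: int) -> bool:
        adj = np.zeros((n, n), dtype=bool)
        adj[ei[:k], ej[:k]] = True
        adj |= adj.T
        return _is_connected(adj)

    if not ok(hi):  # caller guarantees this cannot happen
        raise DataError("graph disconnected even with all positive edges")
    while lo < hi:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid + 1
    return lo


def sparsity_range(cms, step: float = 0.01):
    """Cohort-wide sparsity bounds (s_min, s_max) on a grid of ``step``.

    ``s_min`` is the smallest grid sparsity at which every subject's
    thresholded network is fully connected; ``s_max`` the smallest grid
    sparsity that retains every positive weight of every subject.
    Subjects whose all-positive graph is already disconnected make the
    lower bound undefined and raise a :class:`DataError` naming them.
    """
    cms = list(cms)
    if not cms:
        raise DataError("need at least one connectivity matrix")
    n = cms[0].n
    for cm in cms:
        if cm.n != n:
            raise DataError("all subjects must share the same node set")
    m_total = n * (n - 1) // 2
    grid = np.round(np.arange(step, 1 + step / 2, step), 2)

    k_conn, k_pos, bad = [], [], []
    for idx, cm in enumerate(cms):
        ei, ej = _ranked_positive_edges(cm.weights)
        adj = np.zeros((n, n), dtype=bool)
        adj[ei, ej] = True
        adj |= adj.T
        if not _is_connected(adj):
            bad.append(idx)
            continue
        k_pos.append(len(ei))
        k_conn.append(_min_connected_edge_count(ei, ej, n))
    if bad:
        raise DataError(
            "subjects disconnected even at their all-positive graph: "
            + ", ".join(str(b) for b in bad)
        )

    need_conn, need_pos = max(k_conn), max(k_pos)
    s_min = s_max = None
    for s in grid:
        kept = int(round(s * m_total))
        if s_min is None and kept >= need_conn:
            s_min = float(s)
        if s_max is None and kept >= need_pos:
            s_max = float(s)
        if s_min is not None and s_max is not None:
            break
    return s_min, s_max


# ---------------------------------------------------------------------------
# efficiency kernels


def _pairwise_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths of a boolean adjacency (BFS).

    Breadth-first search over all sources simultaneously via boolean
    matrix products (BLAS float32 under the hood); unreachable pairs
    stay at +inf.
    """
    n = adj.shape[0]
    dist = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    if n < 2 or not adj.any():
        return dist
    a32 = adj.astype(np.float32)
    reach = adj | np.eye(n, dtype=bool)
    d = 1
    while True:
        wider = (reach.astype(np.float32) @ a32) > 0
        wider |= reach
        new = wider & ~reach
        if not new.any():
            break
        d += 1
        dist[new] = d
        reach = wider
    return dist


def _inverse_distance_matrix(adj: np.ndarray) -> np.ndarray:
    dist = _pairwise_distances(adj)
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & (dist > 0)
    inv[finite] = 1.0 / dist[finite]
    return inv


def _global_eff(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    return float(_inverse_distance_matrix(adj).sum() / (n * (n - 1)))


def _nodal_global_eff(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    if n < 2:
        return np.zeros(n)
    return _inverse_distance_matrix(adj).sum(axis=1) / (n - 1)


def _local_eff(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = adj[i]
        if int(nbrs.sum()) < 2:
            continue
        total += _global_eff(adj[np.ix_(nbrs, nbrs)])
    return total / n if n else 0.0


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean inverse shortest-path length over node pairs (integration)."""
    if net.n < 2:
        raise DataError("global efficiency undefined for fewer than 2 nodes")
    return _global_eff(net.adjacency)


def local_efficiency(net: BinaryNetwork) -> float:
    """Mean, over nodes, of the neighbourhood subgraph's global efficiency."""
    return _local_eff(net.adjacency)


def nodal_global_efficiency(net: BinaryNetwork) -> np.ndarray:
    """Per-node mean inverse distance to every other node."""
    return _nodal_global_eff(net.adjacency)


# ---------------------------------------------------------------------------
# null models and small-worldness


def degree_matched_randomize(
    net: BinaryNetwork, seed=None, n_swap_factor: int = 10
) -> BinaryNetwork:
    """Degree-preserving rewiring by attempted double-edge swaps.

    ``n_swap_factor * n_edges`` swaps are attempted; swaps that would
    create a self-loop or a multi-edge are rejected, so the output has
    exactly the input's degree sequence.  Connectedness is not
    enforced.  Rewiring runs through igraph's C implementation driven
    by a seeded Python RNG, so results are reproducible.
    """
    import igraph

    m = net.n_edges
    if m < 2:
        raise DataError("degree-matched rewiring needs at least 2 edges")
    ei, ej = np.nonzero(np.triu(net.adjacency, k=1))
    g = igraph.Graph(n=net.n, edges=list(zip(ei.tolist(), ej.tolist())))
    igraph.set_random_number_generator(_pyrandom.Random(sub_seed(as_rng(seed))))
    try:
        g.rewire(n=n_swap_factor * m, mode="simple")
    finally:
        igraph.set_random_number_generator(_pyrandom)
    adj = np.zeros((net.n, net.n), dtype=bool)
    edges = np.asarray(g.get_edgelist(), dtype=int)
    adj[edges[:, 0], edges[:, 1]] = True
    adj |= adj.T
    if not np.array_equal(adj.sum(axis=1), net.adjacency.sum(axis=1)):
        raise RuntimeError("rewiring changed the degree sequence")  # pragma: no cover
    if np.array_equal(adj, net.adjacency):
        logger.info("rewiring left the graph unchanged (no legal swap found)")
    return BinaryNetwork(net.node_ids, adj, net.sparsity)


def small_world_sigma(
    net: BinaryNetwork,
    n_random: int = 100,
    seed=None,
    n_swap_factor: int = 10,
) -> TopologyMetrics:
    """Small-world index sigma against degree-matched rewired nulls.

    sigma = (locE / mean null locE) / (gE / mean null gE).  A value
    greater than 1 indicates small-world organisation: clustering in
    excess of a degree-matched random graph at comparable path lengths.
    """
    if n_random < 1:
        raise ConfigError("n_random must be >= 1")
    ge = global_efficiency(net)
    loce = local_efficiency(net)
    rng = as_rng(seed)
    null_ge = np.empty(n_random)
    null_loce = np.empty(n_random)
    for k in range(n_random):
        null = degree_matched_randomize(net, seed=rng, n_swap_factor=n_swap_factor)
        null_ge[k] = _global_eff(null.adjacency)
        null_loce[k] = _local_eff(null.adjacency)
    mean_ge, mean_loce = null_ge.mean(), null_loce.mean()
    if mean_ge <= 0 or mean_loce <= 0:
        raise DataError("degenerate graph: null-mean efficiency is zero")
    scaled_ge = ge / mean_ge
    scaled_loce = loce / mean_loce
    if scaled_ge <= 0:
        raise DataError("scaled global efficiency is zero; sigma undefined")
    return TopologyMetrics(
        sparsity=net.sparsity,
        net_ge=ge,
        net_loce=loce,
        scaled_ge=scaled_ge,
        scaled_loce=scaled_loce,
        sigma=scaled_loce / scaled_ge,
        n_random=n_random,
    )


# ---------------------------------------------------------------------------
# sparsity curves


def auc_over_sparsity(curve: MetricCurve) -> float:
    """Trapezoidal integral of a metric over its sparsity grid."""
    s, v = curve.sparsities, curve.values
    if len(s) < 2:
        raise DataError("AUC needs at least two grid points")
    steps = np.diff(s)
    if np.abs(steps - steps[0]).max() > 1e-9:
        raise DataError("sparsity grid must have a uniform step")
    return float(np.trapezoid(v, s))


def metric_curve(
    cm: ConnectivityMatrix,
    sparsities,
    metric: str = "net_gE",
    n_random: int = 100,
    seed=None,
) -> MetricCurve:
    """Evaluate one metric ("net_gE" | "net_locE" | "sigma") over a grid."""
    sparsities = np.asarray(sparsities, dtype=float)
    values = np.empty(len(sparsities))
    rng = as_rng(seed)
    for k, s in enumerate(sparsities):
        net = threshold_by_sparsity(cm, float(s))
        if metric == "net_gE":
            values[k] = global_efficiency(net)
        elif metric == "net_locE":
            values[k] = local_efficiency(net)
        elif metric == "sigma":
            values[k] = small_world_sigma(net, n_random=n_random, seed=rng).sigma
        else:
            raise ConfigError(f"unknown metric {metric!r}")
    return MetricCurve(sparsities, values)
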