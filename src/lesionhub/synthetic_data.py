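"""Synthetic lesion cohorts with the statistical structure the analysis
assumes.

Three generators compose into a cohort:

1. a modular healthy base connectome — block-structured Fisher-z
   weights (4 modules by default) with designated connector nodes that
   carry extra cross-module weight;
2. spatially contiguous lesion "blobs" grown over a k-nearest-neighbour
   adjacency of synthetic 3-D node coordinates, seeded with non-uniform
   per-node probabilities (vascular-style vulnerability: a handful of
   hub nodes — the *effectors* — are strongly over-represented, the way
   middle-cerebral-artery territory dominates real stroke cohorts);
3. a multiplicative forward model, w_ij = base_ij * (1-lp_i)^a *
   (1-lp_j)^a + noise, so lesion fractions act approximately linearly
   on the network — matching the linear-SVR working assumption.

Ground-truth effect signs per (effector, label) come from a
single-node full-deletion oracle rather than being asserted a priori.
``null_mode`` shuffles the lesion patterns across patients *after* the
matrices are generated, destroying the lesion-topology coupling while
preserving both marginals; it is the null condition for calibrating
the permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from ._rng import as_rng
from .network_metrics import (
    ConnectivityMatrix,
    global_efficiency,
    local_efficiency,
    small_world_sigma,
    threshold_by_sparsity,
)
from .lesion_model import LesionPattern

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_healthy_base",
    "generate_lesion_patterns",
    "apply_lesion_forward_model",
    "generate_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the cohort the pipeline is built for: 96 patients,
    180 cortical nodes in 4 modules, sparse contiguous lesions with
    heterogeneous node-wise frequency, and a planted linear coupling
    between lesion pattern and network topology.
    """

    n_nodes: int = 180
    n_modules: int = 4
    n_patients: int = 96
    # block structure of the healthy base (Fisher-z units)
    within_mean: float = 0.6
    within_sd: float = 0.12
    between_mean: float = 0.15
    between_sd: float = 0.12
    n_connectors_per_module: int = 2
    connector_boost: float = 0.35
    # effectors: high-vulnerability hub nodes driving the planted coupling
    n_effectors: int = 6
    effector_placement: str = "connector"  # or "provincial"
    effector_seed_weight: float = 120.0
    seed_weight_sigma: float = 1.0  # lognormal sd of node vulnerability
    # lesion geometry: blobs have a heavily damaged core (the seed node)
    # and a progressively spared penumbra
    knn_k: int = 6
    blob_size_mean: float = 8.0
    blob_size_min: int = 3
    blob_size_max: int = 24
    two_blob_prob: float = 0.3
    lesion_beta_a: float = 4.0
    lesion_beta_b: float = 1.5
    lesion_gradient: float = 0.5  # lp attenuation per step away from the core
    node_volume_voxels: int = 1000
    # forward model
    attenuation_exponent: float = 1.0
    noise_sd: float = 0.08
    # ground-truth oracle
    label_sparsity: float = 0.15
    oracle_n_random: int = 200
    null_mode: bool = False
    seed: int = 0

    def validate(self):
        if min(self.n_nodes, self.n_modules, self.n_patients, self.n_effectors) <= 0:
            raise ConfigError("all counts must be positive")
        if self.within_mean <= self.between_mean:
            raise ConfigError(
                "within-module mean connectivity must exceed the between-module mean"
            )
        if self.effector_placement not in ("connector", "provincial"):
            raise ConfigError(
                f"effector_placement must be 'connector' or 'provincial', "
                f"got {self.effector_placement!r}"
            )
        if self.n_modules * self.n_connectors_per_module > self.n_nodes:
            raise ConfigError("more connectors than nodes")
        if not 0 < self.label_sparsity <= 1:
            raise ConfigError("label_sparsity must lie in (0, 1]")
        return self


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus everything needed to score recovery."""

    config: SyntheticConfig
    base: ConnectivityMatrix
    module_labels: np.ndarray
    coords: np.ndarray
    node_adjacency: np.ndarray  # kNN contiguity used to grow lesion blobs
    connectors: tuple
    effectors: tuple
    matrices: list
    patterns: list
    ground_truth: pd.DataFrame  # columns: node_id, label, expected_sign

    @property
    def node_ids(self) -> tuple:
        return self.base.node_ids


def _stage_rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    # documented fan-out: stage k uses SeedSequence(cfg.seed, spawn_key=(k,))
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class _Geometry:
    module_labels: np.ndarray
    coords: np.ndarray
    adjacency: np.ndarray
    connectors: tuple
    effectors: tuple
    seed_probs: np.ndarray


def _node_ids(cfg) -> tuple:
    width = max(3, len(str(cfg.n_nodes - 1)))
    return tuple(f"n{i:0{width}d}" for i in range(cfg.n_nodes))


def _build_geometry(cfg: SyntheticConfig) -> _Geometry:
    """Module layout, coordinates, contiguity and vulnerability weights.

    Deterministic given ``cfg.seed`` (stage-0 stream), so the base
    connectome and the lesion generator always agree on geometry.
    """
    rng = _stage_rng(cfg, 0)
    n, m = cfg.n_nodes, cfg.n_modules
    sizes = np.full(m, n // m)
    sizes[: n % m] += 1
    labels = np.repeat(np.arange(m), sizes)
    centers = rng.normal(0.0, 1.0, size=(m, 3)) * 4.0
    coords = centers[labels] + rng.normal(0.0, 1.0, size=(n, 3))

    # symmetric k-nearest-neighbour contiguity
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    k = min(cfg.knn_k, n - 1)
    nn = np.argsort(d2, axis=1)[:, :k]
    adj = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    adj[rows, nn.ravel()] = True
    adj |= adj.T

    connectors = []
    for mod in range(m):
        members = np.flatnonzero(labels == mod)
        pick = rng.choice(members, size=min(cfg.n_connectors_per_module, len(members)),
                          replace=False)
        connectors.extend(int(i) for i in np.sort(pick))
    connectors = tuple(connectors)

    if cfg.effector_placement == "connector":
        pool = list(connectors)
    else:
        pool = [i for i in range(n) if i not in connectors]
    # round-robin across modules so effectors spread over the network
    by_module = {}
    for i in pool:
        by_module.setdefault(int(labels[i]), []).append(i)
    effectors = []
    while len(effectors) < cfg.n_effectors and any(by_module.values()):
        for mod in sorted(by_module):
            if by_module[mod] and len(effectors) < cfg.n_effectors:
                effectors.append(by_module[mod].pop(0))
    effectors = tuple(sorted(effectors))

    weights = rng.lognormal(mean=0.0, sigma=cfg.seed_weight_sigma, size=n)
    # effectors carry a fixed (not chance-drawn) vulnerability mass, the
    # way arterial-territory hotspots dominate real lesion overlap maps
    weights[list(effectors)] = cfg.effector_seed_weight
    return _Geometry(labels, coords, adj, connectors, effectors, weights / weights.sum())


def _build_base(cfg: SyntheticConfig, geom: _Geometry) -> ConnectivityMatrix:
    """Block-structured weights with graded connector cross-edges.

    Connector nodes get their cross-module weight distribution shifted
    up by ``connector_boost`` so that only its upper tail clears a
    typical sparsity cutoff: connectors become genuine high-degree
    hubs of the thresholded graph (their removal costs the network a
    sizeable share of its inter-module shortcuts) while retained
    cross-module edges stay a minority of all edges, keeping the
    planted modules detectable.
    """
    rng = _stage_rng(cfg, 1)
    n = cfg.n_nodes
    labels = geom.module_labels
    same = labels[:, None] == labels[None, :]
    mean = np.where(same, cfg.within_mean, cfg.between_mean)
    sd = np.where(same, cfg.within_sd, cfg.between_sd)
    noise = rng.normal(0.0, 1.0, size=(n, n))
    w = mean + sd * noise
    for c in geom.connectors:
        w[c, ~same[c]] += cfg.connector_boost
        w[~same[c], c] += cfg.connector_boost
    w = np.triu(w, 1)
    w = w + w.T
    return ConnectivityMatrix(_node_ids(cfg), w)


def generate_healthy_base(cfg: SyntheticConfig) -> ConnectivityMatrix:
    """Block-structured healthy connectome (Fisher-z weights)."""
    cfg.validate()
    return _build_base(cfg, _build_geometry(cfg))


def _grow_blob(adj: np.ndarray, seed_node: int, size: int, rng):
    """Random connected blob over the contiguity graph.

    Returns the blob nodes together with each node's BFS depth from
    the seed (the lesion "core"), used for the core-penumbra gradient.
    """
    blob = [seed_node]
    in_blob = {seed_node}
    while len(blob) < size:
        frontier = sorted(
            set(j for i in blob for j in np.flatnonzero(adj[i])) - in_blob
        )
        if not frontier:
            break
        nxt = int(rng.choice(frontier))
        blob.append(nxt)
        in_blob.add(nxt)
    # BFS depth from the seed inside the blob
    depth = {seed_node: 0}
    frontier = [seed_node]
    while frontier:
        nxt = []
        for u in frontier:
            for v in np.flatnonzero(adj[u]):
                if v in in_blob and v not in depth:
                    depth[v] = depth[u] + 1
                    nxt.append(v)
        frontier = nxt
    return blob, np.array([depth[b] for b in blob])


def _draw_patterns(cfg: SyntheticConfig, geom: _Geometry) -> list:
    rng = _stage_rng(cfg, 2)
    ids = _node_ids(cfg)
    patterns = []
    for p in range(cfg.n_patients):
        lp = np.zeros(cfg.n_nodes)
        n_blobs = 2 if rng.random() < cfg.two_blob_prob else 1
        for _ in range(n_blobs):
            seed_node = int(rng.choice(cfg.n_nodes, p=geom.seed_probs))
            size = int(np.clip(rng.poisson(cfg.blob_size_mean),
                               cfg.blob_size_min, cfg.blob_size_max))
            blob, depth = _grow_blob(geom.adjacency, seed_node, size, rng)
            frac = rng.beta(cfg.lesion_beta_a, cfg.lesion_beta_b, size=len(blob))
            frac *= cfg.lesion_gradient ** depth  # core damaged, penumbra spared
            lp[blob] = np.maximum(lp[blob], frac)
        patterns.append(
            LesionPattern(
                patient_id=f"p{p:03d}",
                node_ids=ids,
                lp=lp,
                total_volume=float(lp.sum() * cfg.node_volume_voxels),
            )
        )
    return patterns


def generate_lesion_patterns(cfg: SyntheticConfig) -> list:
    """Contiguous heterogeneous lesion patterns for the whole cohort."""
    cfg.validate()
    return _draw_patterns(cfg, _build_geometry(cfg))


def apply_lesion_forward_model(
    base: ConnectivityMatrix, lp, cfg: SyntheticConfig, rng=None
) -> ConnectivityMatrix:
    """Attenuate a base connectome by a lesion pattern, plus edge noise.

    w_ij = base_ij * (1-lp_i)^a * (1-lp_j)^a + N(0, noise_sd), with the
    noise drawn once per (unordered) edge.  ``rng=None`` derives a
    deterministic stream from ``cfg.seed``.
    """
    if isinstance(lp, LesionPattern):
        lp = lp.lp
    lp = np.asarray(lp, dtype=float)
    if lp.shape != (base.n,):
        raise ConfigError("lesion fraction vector does not match the base connectome")
    rng = _stage_rng(cfg, 3) if rng is None else as_rng(rng)
    att = (1.0 - lp) ** cfg.attenuation_exponent
    w = base.weights * np.outer(att, att)
    if cfg.noise_sd > 0:
        noise = np.triu(rng.normal(0.0, cfg.noise_sd, size=w.shape), 1)
        w = w + noise + noise.T
    return ConnectivityMatrix(base.node_ids, w)


def _deletion_oracle(cfg, base, effectors, ids) -> pd.DataFrame:
    """Expected effect sign per (effector, label) from full deletion.

    The oracle compares each topology metric between the intact base
    and the base with one effector fully lesioned (lp = 1, no noise),
    thresholded at the representative sparsity.  The sigma oracle uses
    ``oracle_n_random`` rewired nulls (more than the per-patient
    default) to keep its Monte-Carlo sign error small.
    """
    quiet = replace(cfg, noise_sd=0.0)
    s = cfg.label_sparsity

    def metrics(cm, tag):
        net = threshold_by_sparsity(cm, s)
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=(4, tag))
        )
        tm = small_world_sigma(net, n_random=cfg.oracle_n_random, seed=rng)
        return {"net_gE": tm.net_ge, "net_locE": tm.net_loce, "sigma": tm.sigma}

    base_vals = metrics(base, 0)
    rows = []
    for e in effectors:
        lp = np.zeros(base.n)
        lp[e] = 1.0
        lesioned = apply_lesion_forward_model(base, lp, quiet, rng=0)
        vals = metrics(lesioned, e + 1)
        for label in ("net_gE", "net_locE", "sigma"):
            delta = vals[label] - base_vals[label]
            rows.append(
                {
                    "node_id": ids[e],
                    "label": label,
                    "expected_sign": int(np.sign(delta)) if delta != 0 else 0,
                    "delta": delta,
                }
            )
    return pd.DataFrame(rows, columns=["node_id", "label", "expected_sign", "delta"])


def generate_cohort(cfg: SyntheticConfig, ground_truth: bool = True) -> SyntheticCohort:
    """Compose geometry, base, lesions and forward model into a cohort.

    ``null_mode`` reassigns the lesion patterns across patients after
    the matrices are generated: the multiset of patterns and the
    multiset of matrices are both unchanged, but their pairing — and
    hence the lesion-topology coupling — is destroyed.  Ground truth is
    only computed for coupled cohorts (and can be disabled entirely).
    """
    cfg.validate()
    geom = _build_geometry(cfg)
    base = _build_base(cfg, geom)
    patterns = _draw_patterns(cfg, geom)
    noise_rngs = [
        np.random.default_rng(child)
        for child in np.random.SeedSequence(cfg.seed, spawn_key=(5,)).spawn(cfg.n_patients)
    ]
    matrices = [
        apply_lesion_forward_model(base, pat, cfg, rng=r)
        for pat, r in zip(patterns, noise_rngs)
    ]
    if cfg.null_mode:
        shuffle_rng = _stage_rng(cfg, 6)
        order = shuffle_rng.permutation(cfg.n_patients)
        patterns = [
            LesionPattern(
                patient_id=f"p{i:03d}",
                node_ids=patterns[j].node_ids,
                lp=patterns[j].lp,
                total_volume=patterns[j].total_volume,
            )
            for i, j in enumerate(order)
        ]
    ids = _node_ids(cfg)
    if ground_truth and not cfg.null_mode:
        gt = _deletion_oracle(cfg, base, geom.effectors, ids)
    else:
        gt = pd.DataFrame(columns=["node_id", "label", "expected_sign", "delta"])
    return SyntheticCohort(
        config=cfg,
        base=base,
        module_labels=geom.module_labels,
        coords=geom.coords,
        node_adjacency=geom.adjacency,
        connectors=tuple(ids[c] for c in geom.connectors),
        effectors=tuple(ids[e] for e in geom.effectors),
        matrices=matrices,
        patterns=patterns,
        ground_truth=gt,
    )
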