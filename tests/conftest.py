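"""Shared fixtures and builders for the test suite."""

import numpy as np
import pytest

from lesionhub import BinaryNetwork, ConnectivityMatrix, LesionModelResult


def bn_from_adj(adj, sparsity=None) -> BinaryNetwork:
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    if sparsity is None:
        sparsity = adj.sum() / (n * (n - 1)) if n > 1 else 0.0
    return BinaryNetwork(tuple(str(i) for i in range(n)), adj, float(sparsity))


def bn_from_edges(n, edges) -> BinaryNetwork:
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return bn_from_adj(adj)


def cm_from_weights(w) -> ConnectivityMatrix:
    w = np.asarray(w, dtype=float)
    return ConnectivityMatrix(tuple(str(i) for i in range(w.shape[0])), w)


def random_symmetric(n, rng, loc=0.0, scale=0.5):
    w = rng.normal(loc, scale, size=(n, n))
    w = np.triu(w, 1)
    return w + w.T


def make_result(feature_ids, significant, sign, label="label") -> LesionModelResult:
    """Minimal LesionModelResult for pure-logic tests."""
    p = len(feature_ids)
    sig = np.asarray(significant, dtype=bool)
    sgn = np.asarray(sign, dtype=int)
    z = np.zeros(p)
    return LesionModelResult(
        label_name=label,
        patient_ids=("p0", "p1", "p2"),
        feature_ids=tuple(feature_ids),
        actual=np.zeros(3),
        predicted=np.zeros(3),
        accuracy_r=0.0,
        p_value=1.0,
        n_permutations=0,
        weights=sgn.astype(float),
        bias=0.0,
        weight_lo=z - 1,
        weight_hi=z + 1,
        significant=sig,
        sign=sgn,
        null_accuracies=np.zeros(1),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
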