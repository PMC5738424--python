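"""Multivariate lesion models: SVR prediction of network topology from
lesion patterns, with leave-one-out cross-validation, permutation
inference, feature-weight significance and lesion-hub classification.

The model is a linear epsilon-SVR, Y = w^T X + b, trained with the
cited implementation's default parameters (C = 1, epsilon = 0.1) on
per-node lesion-percentage features (already on a common [0, 1] scale,
so no standardisation is applied).  Prediction accuracy is the Pearson
correlation between leave-one-out predictions and the actual labels;
its one-tailed significance and the per-feature two-tailed weight
significance both come from one shared set of label permutations:

    P = (#{null accuracy >= actual accuracy} + 1) / (n_perm + 1)

and a feature weight is significant when it falls below the 2.5th or
above the 97.5th percentile of its permutation null.

Nodes whose weights are significant are "lesion hubs", classified by
sign pattern: damage shifting the network towards a more integrated
topology (lower locE or sigma, higher gE) versus a more segregated one
(the opposite signs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from scipy import stats
from sklearn.svm import SVR

from .errors import ConfigError, DataError
from ._rng import as_rng, spawn_rngs
from .network_metrics import (
    ConnectivityMatrix,
    MetricCurve,
    auc_over_sparsity,
    global_efficiency,
    local_efficiency,
    small_world_sigma,
    threshold_by_sparsity,
)

SVR_C = 1.0
SVR_EPSILON = 0.1
LABEL_NAMES = ("sigma", "net_gE", "net_locE")

__all__ = [
    "LesionPattern",
    "FeatureMatrix",
    "SVRModel",
    "LesionModelResult",
    "compute_lesion_percentages",
    "assemble_features",
    "train_svr",
    "loocv_accuracy",
    "permutation_model_significance",
    "feature_weight_significance",
    "fit_lesion_model",
    "classify_lesion_hubs",
    "split_half_validation",
    "group_topology_comparison",
    "compute_topology_labels",
    "run_lesion_analysis",
    "LesionAnalysis",
]


@dataclass(frozen=True)
class LesionPattern:
    """Per-node lesion fractions for one patient.

    ``lp[i]`` is the fraction of node i's voxels overlapped by the
    lesion mask; ``total_volume`` the patient's total lesioned-voxel
    count (or mm^3 — any consistent unit).
    """

    patient_id: str
    node_ids: tuple
    lp: np.ndarray
    total_volume: float

    def __post_init__(self):
        lp = np.asarray(self.lp, dtype=float)
        if lp.ndim != 1 or len(lp) != len(self.node_ids):
            raise DataError("lesion fractions must be 1-D, one per node")
        if np.any(lp < 0) or np.any(lp > 1) or not np.all(np.isfinite(lp)):
            raise DataError(f"lesion fractions outside [0, 1] for {self.patient_id}")
        if self.total_volume < 0:
            raise DataError("total lesion volume must be non-negative")
        lp = lp.copy()
        lp.flags.writeable = False
        object.__setattr__(self, "node_ids", tuple(str(i) for i in self.node_ids))
        object.__setattr__(self, "lp", lp)


@dataclass(frozen=True)
class FeatureMatrix:
    """Patients x features design matrix for the lesion models."""

    patient_ids: tuple
    feature_ids: tuple
    X: np.ndarray
    dropped_features: tuple = ()

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        if X.shape != (len(self.patient_ids), len(self.feature_ids)):
            raise DataError("feature matrix shape does not match ids")
        X = X.copy()
        X.flags.writeable = False
        object.__setattr__(self, "X", X)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


@dataclass(frozen=True)
class SVRModel:
    """Fitted linear epsilon-SVR: weights w, bias b."""

    weights: np.ndarray
    bias: float
    C: float = SVR_C
    epsilon: float = SVR_EPSILON

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias


@dataclass(frozen=True)
class LesionModelResult:
    """Everything the permutation pipeline produces for one label."""

    label_name: str
    patient_ids: tuple
    feature_ids: tuple
    actual: np.ndarray
    predicted: np.ndarray
    accuracy_r: float
    p_value: float
    n_permutations: int
    weights: np.ndarray
    bias: float
    weight_lo: np.ndarray  # null 2.5th percentile, per feature
    weight_hi: np.ndarray  # null 97.5th percentile, per feature
    significant: np.ndarray
    sign: np.ndarray
    null_accuracies: np.ndarray = field(repr=False, default=None)

    def feature_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "weight": self.weights,
                "null_p2.5": self.weight_lo,
                "null_p97.5": self.weight_hi,
                "significant": self.significant,
                "sign": self.sign,
            },
            index=pd.Index(self.feature_ids, name="feature_id"),
        )


# ---------------------------------------------------------------------------
# features


def compute_lesion_percentages(
    lesion_mask, parcellation, patient_id: str = "patient", labels=None
) -> LesionPattern:
    """Per-parcel lesion fraction from a mask and a parcellation volume.

    Both arguments are NIfTI images (anything with ``get_fdata`` and
    ``affine``) or plain integer arrays on the same grid.  Nonzero mask
    voxels count as lesioned.  ``labels`` optionally fixes the expected
    parcel labels; a listed parcel absent from the volume is an error.
    """
    mask_data, mask_aff = _volume_data(lesion_mask)
    parc_data, parc_aff = _volume_data(parcellation)
    if mask_data.shape != parc_data.shape:
        raise DataError(
            f"grid mismatch: mask {mask_data.shape} vs parcellation {parc_data.shape}"
        )
    if mask_aff is not None and parc_aff is not None and not np.allclose(
        mask_aff, parc_aff, atol=1e-6
    ):
        raise DataError("affine mismatch between lesion mask and parcellation")
    if mask_data.ndim != 3:
        raise DataError(f"expected a 3-D volume, got {mask_data.ndim}-D")

    parc = np.rint(parc_data).astype(int)
    lesioned = mask_data != 0
    found = np.unique(parc[parc > 0])
    if labels is None:
        labels = found
    else:
        labels = np.asarray(list(labels), dtype=int)
        missing = sorted(set(labels) - set(found))
        if missing:
            raise DataError(f"empty parcel(s) in parcellation: {missing}")
    counts = np.bincount(parc.ravel(), minlength=labels.max() + 1)
    hits = np.bincount(parc.ravel(), weights=lesioned.ravel(), minlength=labels.max() + 1)
    lp = hits[labels] / counts[labels]
    return LesionPattern(
        patient_id=patient_id,
        node_ids=tuple(str(l) for l in labels),
        lp=lp,
        total_volume=float(lesioned.sum()),
    )


def _volume_data(vol):
    if hasattr(vol, "get_fdata"):
        return np.asarray(vol.get_fdata()), np.asarray(vol.affine)
    return np.asarray(vol), None


def assemble_features(
    patterns, covariates=(), covariate_values=None
) -> FeatureMatrix:
    """Stack lesion patterns into a design matrix.

    Node features lesioned in no patient are dropped (and recorded in
    ``dropped_features``).  ``covariates`` may include "total_volume"
    (taken from the patterns) plus any key of ``covariate_values``
    (e.g. age, time post onset); each covariate is min-max scaled to
    [0, 1] so it stays commensurate with the lesion fractions.
    """
    patterns = list(patterns)
    if len(patterns) < 3:
        raise DataError(f"need at least 3 patients, got {len(patterns)}")
    node_ids = patterns[0].node_ids
    for p in patterns[1:]:
        if p.node_ids != node_ids:
            raise DataError(f"inconsistent node sets (patient {p.patient_id})")
    X = np.vstack([p.lp for p in patterns])
    nonzero = X.any(axis=0)
    dropped = tuple(np.array(node_ids)[~nonzero])
    X = X[:, nonzero]
    kept_ids = list(np.array(node_ids)[nonzero])
    if X.shape[1] == 0:
        raise DataError("all node features are zero: no patient has any lesion")

    covariate_values = dict(covariate_values or {})
    cols = []
    for name in covariates:
        if name == "total_volume":
            v = np.array([p.total_volume for p in patterns], dtype=float)
        elif name in covariate_values:
            v = np.asarray(covariate_values[name], dtype=float)
            if len(v) != len(patterns):
                raise DataError(f"covariate {name!r} length != number of patients")
        else:
            raise ConfigError(f"no values supplied for covariate {name!r}")
        span = v.max() - v.min()
        if span > 0:
            v = (v - v.min()) / span
        else:
            warnings.warn(f"covariate {name!r} is constant; scaled to all zeros")
            v = np.zeros_like(v)
        cols.append(v)
        kept_ids.append(name)
    if cols:
        X = np.column_stack([X] + cols)
    return FeatureMatrix(
        patient_ids=tuple(p.patient_id for p in patterns),
        feature_ids=tuple(kept_ids),
        X=X,
        dropped_features=dropped,
    )


# ---------------------------------------------------------------------------
# SVR core


def _as_X(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.X
    return np.ascontiguousarray(features, dtype=float)


def _svr() -> SVR:
    return SVR(kernel="linear", C=SVR_C, epsilon=SVR_EPSILON)


def _fit_weights(X: np.ndarray, y: np.ndarray):
    """Fit the SVR on the standardized label and map back to raw units.

    Network-topology labels live on arbitrary scales (gE spreads over
    ~0.01 while sigma spreads over ~0.05), and the epsilon-insensitive
    tube of the default parameters (epsilon = 0.1) is only meaningful
    relative to the label spread: training on the z-scored label makes
    epsilon mean "0.1 label standard deviations" for every label.  The
    returned weights/bias are rescaled to raw label units, so signs and
    predictions are unaffected by the transform.
    """
    mu, sd = y.mean(), y.std()
    if sd == 0:
        return np.zeros(X.shape[1]), float(mu)
    m = _svr().fit(X, (y - mu) / sd)
    return m.coef_.ravel() * sd, float(m.intercept_[0]) * sd + mu


def train_svr(features, y) -> SVRModel:
    """Linear epsilon-SVR with default parameters (C=1, epsilon=0.1).

    Lesion-percentage features already share the [0, 1] scale, so no
    feature standardisation is applied; the label is z-scored
    internally (see :func:`_fit_weights`) and weights returned in raw
    label units.
    """
    X = _as_X(features)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise DataError("X rows and y length differ")
    if X.shape[0] < 3:
        raise DataError("need at least 3 training samples")
    if np.all(np.ptp(X, axis=0) == 0):
        warnings.warn("all features are constant: degenerate fit, zero weights")
    w, b = _fit_weights(X, y)
    return SVRModel(weights=w, bias=b)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("Pearson r undefined for a constant vector; returning 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _loocv_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = len(y)
    pred = np.empty(n)
    idx = np.arange(n)
    model = _svr()
    for i in range(n):
        tr = idx != i
        yt = y[tr]
        mu, sd = yt.mean(), yt.std()  # fold-internal standardization
        if sd == 0:
            pred[i] = mu
            continue
        model.fit(X[tr], (yt - mu) / sd)
        pred[i] = model.predict(X[i : i + 1])[0] * sd + mu
    return pred


def loocv_accuracy(features, y):
    """Leave-one-out predictions and their Pearson accuracy.

    Each patient is predicted by a model trained on all the others;
    accuracy is r(predicted, actual) over the assembled prediction
    vector.  Constant vectors yield r = 0 with a warning.
    """
    X = _as_X(features)
    y = np.asarray(y, dtype=float)
    if len(y) != X.shape[0]:
        raise DataError("X rows and y length differ")
    if len(y) < 5:
        raise DataError(f"LOOCV needs at least 5 patients, got {len(y)}")
    with sklearn.config_context(assume_finite=True):
        pred = _loocv_predictions(X, y)
    return pred, _pearson(pred, y)


def _perm_pvalue(actual: float, null: np.ndarray) -> float:
    """One-tailed permutation P: (#{null >= actual} + 1) / (n + 1)."""
    return (int(np.sum(null >= actual)) + 1) / (len(null) + 1)


def _permutation_pass(X, y, n_perm, seed, collect_weights: bool):
    """Shared permutation engine.

    Draws one label permutation per iteration from ``default_rng(seed)``
    — the identical stream whether or not weights are collected, which
    is what lets model significance and feature-weight significance
    share the same shuffles.
    """
    rng = as_rng(seed)
    n, p = X.shape
    null_r = np.empty(n_perm)
    null_w = np.empty((n_perm, p)) if collect_weights else None
    with sklearn.config_context(assume_finite=True):
        for t in range(n_perm):
            yp = y[rng.permutation(n)]
            null_r[t] = _pearson(_loocv_predictions(X, yp), yp)
            if collect_weights:
                null_w[t], _ = _fit_weights(X, yp)
    return null_r, null_w


def permutation_model_significance(features, y, n_perm: int = 1000, seed=None):
    """One-tailed permutation P of the LOOCV accuracy.

    Returns ``(p_value, actual_r, null_accuracies)``.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    X = _as_X(features)
    y = np.asarray(y, dtype=float)
    _, actual_r = loocv_accuracy(X, y)
    null_r, _ = _permutation_pass(X, y, n_perm, seed, collect_weights=False)
    return _perm_pvalue(actual_r, null_r), actual_r, null_r


def feature_weight_significance(features, y, n_perm: int = 1000, seed=None) -> pd.DataFrame:
    """Two-tailed feature-weight significance from the shared permutations.

    A weight is significant when it falls outside the [2.5, 97.5]
    percentile band of its own permutation null (full-data refits on
    shuffled labels, same shuffles as the model-significance test).
    """
    if n_perm < 40:
        warnings.warn(
            f"n_perm={n_perm} gives poor resolution for 2.5/97.5 percentiles"
        )
    X = _as_X(features)
    y = np.asarray(y, dtype=float)
    with sklearn.config_context(assume_finite=True):
        w, _ = _fit_weights(X, y)
    _, null_w = _permutation_pass(X, y, n_perm, seed, collect_weights=True)
    lo, hi = np.percentile(null_w, [2.5, 97.5], axis=0)
    sig = (w < lo) | (w > hi)
    ids = features.feature_ids if isinstance(features, FeatureMatrix) else range(X.shape[1])
    return pd.DataFrame(
        {
            "weight": w,
            "null_p2.5": lo,
            "null_p97.5": hi,
            "significant": sig,
            "sign": np.sign(w).astype(int),
        },
        index=pd.Index(ids, name="feature_id"),
    )


def fit_lesion_model(
    features, y, label_name: str = "label", n_perm: int = 1000, seed=None
) -> LesionModelResult:
    """Full pipeline for one label: LOOCV accuracy, permutation P and
    feature-weight significance, all from one pass over the shared
    permutations."""
    X = _as_X(features)
    y = np.asarray(y, dtype=float)
    pred, actual_r = loocv_accuracy(X, y)
    with sklearn.config_context(assume_finite=True):
        w, b = _fit_weights(X, y)
    null_r, null_w = _permutation_pass(X, y, n_perm, seed, collect_weights=True)
    lo, hi = np.percentile(null_w, [2.5, 97.5], axis=0)
    if isinstance(features, FeatureMatrix):
        patient_ids, feature_ids = features.patient_ids, features.feature_ids
    else:
        patient_ids = tuple(str(i) for i in range(X.shape[0]))
        feature_ids = tuple(str(j) for j in range(X.shape[1]))
    return LesionModelResult(
        label_name=label_name,
        patient_ids=patient_ids,
        feature_ids=feature_ids,
        actual=y.copy(),
        predicted=pred,
        accuracy_r=actual_r,
        p_value=_perm_pvalue(actual_r, null_r),
        n_permutations=n_perm,
        weights=w,
        bias=b,
        weight_lo=lo,
        weight_hi=hi,
        significant=(w < lo) | (w > hi),
        sign=np.sign(w).astype(int),
        null_accuracies=null_r,
    )


# ---------------------------------------------------------------------------
# hub classification and validations


def classify_lesion_hubs(results) -> pd.DataFrame:
    """Classify significant features into lesion-effect classes.

    ``results`` maps the label names "net_locE", "net_gE" and "sigma"
    to their :class:`LesionModelResult`.  A feature is an *integration*
    hub when its lesion shifts the network towards a more integrated
    topology — significant negative weight for net_locE or sigma, or
    significant positive weight for net_gE — and a *segregation* hub
    for the opposite signs.  Features matching both patterns at once
    are flagged "unclassified".  Only features significant in at least
    one model appear in the table.
    """
    required = {"net_locE", "net_gE", "sigma"}
    if set(results) != required:
        raise DataError(f"expected results for exactly {sorted(required)}")
    ref = results["net_locE"].feature_ids
    for name in ("net_gE", "sigma"):
        if results[name].feature_ids != ref:
            raise DataError(f"feature set of {name!r} differs from net_locE")

    rows = []
    for k, feat in enumerate(ref):
        sig = {n: bool(results[n].significant[k]) for n in required}
        sgn = {n: int(results[n].sign[k]) for n in required}
        if not any(sig.values()):
            continue
        integration = (
            (sig["net_locE"] and sgn["net_locE"] < 0)
            or (sig["sigma"] and sgn["sigma"] < 0)
            or (sig["net_gE"] and sgn["net_gE"] > 0)
        )
        segregation = (
            (sig["net_locE"] and sgn["net_locE"] > 0)
            or (sig["sigma"] and sgn["sigma"] > 0)
            or (sig["net_gE"] and sgn["net_gE"] < 0)
        )
        if integration and segregation:
            effect = "unclassified"
        elif integration:
            effect = "integration"
        else:
            effect = "segregation"
        rows.append(
            {
                "feature_id": feat,
                "locE_sig": sig["net_locE"],
                "locE_sign": sgn["net_locE"],
                "gE_sig": sig["net_gE"],
                "gE_sign": sgn["net_gE"],
                "sigma_sig": sig["sigma"],
                "sigma_sign": sgn["sigma"],
                "effect_class": effect,
            }
        )
    cols = [
        "feature_id",
        "locE_sig",
        "locE_sign",
        "gE_sig",
        "gE_sign",
        "sigma_sig",
        "sigma_sign",
        "effect_class",
    ]
    return pd.DataFrame(rows, columns=cols).set_index("feature_id")


def split_half_validation(features, y, label_name="label", n_perm: int = 1000, seed=None):
    """Random half-split of the patients, full pipeline per half."""
    X = _as_X(features)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise DataError(f"split-half validation needs at least 10 patients, got {n}")
    rng = as_rng(seed)
    perm = rng.permutation(n)
    halves = perm[: n // 2], perm[n // 2 :]
    out = []
    for h, idx in enumerate(halves):
        idx = np.sort(idx)
        if isinstance(features, FeatureMatrix):
            sub = FeatureMatrix(
                tuple(np.array(features.patient_ids)[idx]),
                features.feature_ids,
                X[idx],
                features.dropped_features,
            )
        else:
            sub = X[idx]
        out.append(
            fit_lesion_model(sub, y[idx], f"{label_name}/half{h + 1}", n_perm, seed=rng)
        )
    return tuple(out)


def group_topology_comparison(
    patient_curves, control_curves, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sample t-test per sparsity level with Benjamini–Hochberg FDR.

    Both groups supply one :class:`MetricCurve` per subject on a common
    grid.  Returns one row per sparsity with raw p, BH-adjusted p,
    significance at ``alpha`` and the direction of the patient-group
    difference.
    """
    from statsmodels.stats.multitest import multipletests

    patient_curves, control_curves = list(patient_curves), list(control_curves)
    if len(patient_curves) < 2 or len(control_curves) < 2:
        raise DataError("each group needs at least 2 subjects")
    grid = patient_curves[0].sparsities
    for c in patient_curves + control_curves:
        if len(c.sparsities) != len(grid) or np.abs(c.sparsities - grid).max() > 1e-9:
            raise DataError("all curves must share one sparsity grid")
    P = np.vstack([c.values for c in patient_curves])
    C = np.vstack([c.values for c in control_curves])
    t, p = stats.ttest_ind(P, C, axis=0)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "sparsity": grid,
            "mean_patient": P.mean(axis=0),
            "mean_control": C.mean(axis=0),
            "t": t,
            "p": p,
            "p_fdr": p_adj,
            "significant": reject,
            "direction": np.where(P.mean(axis=0) < C.mean(axis=0), "decrease", "increase"),
        }
    )


# ---------------------------------------------------------------------------
# end-to-end orchestration


def compute_topology_labels(
    cms,
    labels=LABEL_NAMES,
    sparsity: float = 0.15,
    auc_range=None,
    auc_step: float = 0.01,
    n_random: int = 100,
    seed=None,
) -> pd.DataFrame:
    """Per-patient topology labels at one sparsity or as AUC over a range.

    With ``auc_range=(s1, s2)`` each metric is integrated over the grid
    ``s1..s2`` (step ``auc_step``) instead of evaluated at ``sparsity``.
    Returns a patients x labels DataFrame.
    """
    cms = list(cms)
    unknown = set(labels) - set(LABEL_NAMES)
    if unknown:
        raise ConfigError(f"unknown labels: {sorted(unknown)}")
    rngs = spawn_rngs(seed, len(cms))
    out = {name: np.empty(len(cms)) for name in labels}
    for i, cm in enumerate(cms):
        if auc_range is not None:
            s1, s2 = auc_range
            grid = np.round(np.arange(s1, s2 + auc_step / 2, auc_step), 2)
            nets = [threshold_by_sparsity(cm, float(s)) for s in grid]
            for name in labels:
                if name == "net_gE":
                    vals = [global_efficiency(n) for n in nets]
                elif name == "net_locE":
                    vals = [local_efficiency(n) for n in nets]
                else:
                    vals = [
                        small_world_sigma(n, n_random=n_random, seed=rngs[i]).sigma
                        for n in nets
                    ]
                out[name][i] = auc_over_sparsity(MetricCurve(grid, np.asarray(vals)))
        else:
            net = threshold_by_sparsity(cm, sparsity)
            tm = None
            if "sigma" in labels:
                tm = small_world_sigma(net, n_random=n_random, seed=rngs[i])
            for name in labels:
                if name == "net_gE":
                    out[name][i] = tm.net_ge if tm else global_efficiency(net)
                elif name == "net_locE":
                    out[name][i] = tm.net_loce if tm else local_efficiency(net)
                else:
                    out[name][i] = tm.sigma
    return pd.DataFrame(out, index=pd.Index(range(len(cms)), name="patient"))


@dataclass(frozen=True)
class LesionAnalysis:
    """Bundle of everything one end-to-end run produces."""

    label_table: pd.DataFrame
    features: FeatureMatrix
    results: dict
    hub_table: pd.DataFrame | None
    seed: object


def run_lesion_analysis(
    cms,
    patterns,
    labels=LABEL_NAMES,
    sparsity: float = 0.15,
    auc_range=None,
    auc_step: float = 0.01,
    n_random: int = 100,
    n_perm: int = 1000,
    covariates=("total_volume",),
    covariate_values=None,
    seed=None,
) -> LesionAnalysis:
    """Topology labels -> features -> three lesion models -> hub table.

    The hub table is produced only when all three canonical labels are
    requested; otherwise it is ``None``.
    """
    cms, patterns = list(cms), list(patterns)
    if len(cms) != len(patterns):
        raise DataError("one connectivity matrix per lesion pattern required")
    rng_labels, rng_fit = spawn_rngs(seed, 2)
    table = compute_topology_labels(
        cms,
        labels=labels,
        sparsity=sparsity,
        auc_range=auc_range,
        auc_step=auc_step,
        n_random=n_random,
        seed=rng_labels,
    )
    table.index = pd.Index([p.patient_id for p in patterns], name="patient")
    features = assemble_features(patterns, covariates, covariate_values)
    results = {}
    fit_rngs = spawn_rngs(rng_fit, len(labels))
    for name, r in zip(labels, fit_rngs):
        results[name] = fit_lesion_model(
            features, table[name].to_numpy(), name, n_perm=n_perm, seed=r
        )
    hub_table = None
    if set(labels) == set(LABEL_NAMES):
        hub_table = classify_lesion_hubs(results)
    return LesionAnalysis(table, features, results, hub_table, seed)
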