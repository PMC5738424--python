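"""Lesion-model tests: feature assembly, SVR fitting, LOOCV,
permutation inference and hub classification.

The SVR oracle solves the epsilon-insensitive primal objective
numerically (convex in (w, b)); permutation calibration at scale is
exercised in the acceptance suite.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import lesionhub as lh
from lesionhub.errors import ConfigError, DataError
from lesionhub.lesion_model import _perm_pvalue, SVR_C, SVR_EPSILON

from conftest import make_result


def make_patterns(lp_matrix, node_ids=None, volumes=None):
    lp_matrix = np.asarray(lp_matrix, dtype=float)
    n_nodes = lp_matrix.shape[1]
    node_ids = node_ids or tuple(f"n{i}" for i in range(n_nodes))
    out = []
    for k, row in enumerate(lp_matrix):
        vol = volumes[k] if volumes is not None else float(row.sum() * 100)
        out.append(lh.LesionPattern(f"p{k}", node_ids, row, vol))
    return out


# ---------------------------------------------------------------------------
# lesion percentages from volumes


class TestComputeLesionPercentages:
    def _images(self, mask, parc, mask_affine=None, parc_affine=None):
        import nibabel as nib

        eye = np.eye(4)
        return (
            nib.Nifti1Image(mask.astype(np.int16), mask_affine if mask_affine is not None else eye),
            nib.Nifti1Image(parc.astype(np.int16), parc_affine if parc_affine is not None else eye),
        )

    def test_fractions(self):
        parc = np.zeros((10, 10, 10))
        parc[:2] = 1  # 200 voxels
        parc[2:4] = 2
        mask = np.zeros_like(parc)
        mask[0, :5] = 1  # 50 voxels inside parcel 1
        mimg, pimg = self._images(mask, parc)
        pat = lh.compute_lesion_percentages(mimg, pimg, patient_id="x")
        assert pat.node_ids == ("1", "2")
        assert pat.lp[0] == pytest.approx(0.25)
        assert pat.lp[1] == 0.0
        assert pat.total_volume == 50

    def test_no_overlap_and_full_overlap(self):
        parc = np.zeros((6, 6, 6))
        parc[:3] = 1
        mimg, pimg = self._images(np.zeros_like(parc), parc)
        pat = lh.compute_lesion_percentages(mimg, pimg)
        assert np.all(pat.lp == 0) and pat.total_volume == 0
        mimg, pimg = self._images(parc.copy(), parc)
        pat = lh.compute_lesion_percentages(mimg, pimg)
        assert pat.lp[0] == 1.0

    def test_affine_mismatch(self):
        parc = np.ones((4, 4, 4))
        aff = np.eye(4)
        aff2 = np.diag([2.0, 1, 1, 1])
        mimg, pimg = self._images(parc, parc, mask_affine=aff, parc_affine=aff2)
        with pytest.raises(DataError, match="affine"):
            lh.compute_lesion_percentages(mimg, pimg)

    def test_grid_mismatch(self):
        mimg, _ = self._images(np.ones((4, 4, 4)), np.ones((4, 4, 4)))
        _, pimg = self._images(np.ones((5, 5, 5)), np.ones((5, 5, 5)))
        with pytest.raises(DataError, match="grid"):
            lh.compute_lesion_percentages(mimg, pimg)

    def test_missing_expected_parcel(self):
        parc = np.ones((4, 4, 4))
        mimg, pimg = self._images(np.zeros_like(parc), parc)
        with pytest.raises(DataError, match="empty parcel"):
            lh.compute_lesion_percentages(mimg, pimg, labels=[1, 7])

    def test_plain_arrays_accepted(self):
        parc = np.ones((4, 4, 4))
        mask = np.zeros_like(parc)
        mask[0, 0, 0] = 1
        pat = lh.compute_lesion_percentages(mask, parc)
        assert pat.lp[0] == pytest.approx(1 / 64)


class TestAssembleFeatures:
    def test_drops_never_lesioned_nodes(self):
        lp = np.zeros((5, 6))
        lp[:, 0] = [0.1, 0, 0.3, 0, 0.2]
        lp[:, 2] = [0, 0.5, 0, 0, 0]
        lp[:, 5] = 0.05
        feats = lh.assemble_features(make_patterns(lp))
        assert feats.dropped_features == ("n1", "n3", "n4")
        assert feats.feature_ids == ("n0", "n2", "n5")
        assert feats.X.shape == (5, 3)

    def test_total_volume_covariate_scaled(self):
        lp = np.zeros((4, 3))
        lp[:, 0] = [0.1, 0.2, 0.3, 0.4]
        pats = make_patterns(lp, volumes=[10.0, 20.0, 40.0, 50.0])
        feats = lh.assemble_features(pats, covariates=("total_volume",))
        assert feats.feature_ids[-1] == "total_volume"
        col = feats.X[:, -1]
        assert col.min() == 0.0 and col.max() == 1.0
        assert col[1] == pytest.approx(0.25)

    def test_external_covariate(self):
        lp = np.tile([[0.2, 0.0]], (4, 1))
        lp[:, 0] += np.arange(4) * 0.01
        feats = lh.assemble_features(
            make_patterns(lp),
            covariates=("age",),
            covariate_values={"age": [20, 40, 60, 80]},
        )
        assert np.allclose(feats.X[:, -1], [0, 1 / 3, 2 / 3, 1])

    def test_unknown_covariate(self):
        lp = np.tile([[0.2]], (4, 1))
        with pytest.raises(ConfigError, match="age"):
            lh.assemble_features(make_patterns(lp), covariates=("age",))

    def test_too_few_patients(self):
        with pytest.raises(DataError):
            lh.assemble_features(make_patterns(np.ones((2, 3))))

    def test_all_lesion_free_error(self):
        with pytest.raises(DataError, match="no patient"):
            lh.assemble_features(make_patterns(np.zeros((4, 3))))

    def test_constant_covariate_warns(self):
        lp = np.tile([[0.2]], (4, 1))
        lp[:, 0] += np.arange(4) * 0.01
        pats = make_patterns(lp, volumes=[5.0] * 4)
        with pytest.warns(UserWarning, match="constant"):
            feats = lh.assemble_features(pats, covariates=("total_volume",))
        assert np.all(feats.X[:, -1] == 0)


# ---------------------------------------------------------------------------
# SVR


class TestTrainSVR:
    def test_noiseless_line_matches_qp_oracle(self):
        x = np.arange(0, 1.01, 0.1).reshape(-1, 1)
        y = 2.0 * x.ravel()
        mu, sd = y.mean(), y.std()
        z = (y - mu) / sd
        model = lh.train_svr(x, y)

        # independent numerical solution of the convex primal on the
        # standardized label, mapped to raw units for comparison
        def primal(p):
            resid = np.abs(z - x.ravel() * p[0] - p[1]) - SVR_EPSILON
            return 0.5 * p[0] ** 2 + SVR_C * np.clip(resid, 0, None).sum()

        best = min(
            (
                optimize.minimize(
                    primal, start, method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
                )
                for start in ([2.0 / sd, -mu / sd], [1.0, 0.0], [0.0, 0.0])
            ),
            key=lambda r: r.fun,
        )
        ours = primal([model.weights[0] / sd, (model.bias - mu) / sd])
        assert ours == pytest.approx(best.fun, abs=1e-3)
        assert 1.5 <= model.weights[0] <= 2.05
        # predictions stay inside a slack-consistent band
        assert np.max(np.abs(model.predict(x) - y)) <= SVR_EPSILON * sd + 0.1

    def test_constant_labels(self, rng):
        X = rng.random((8, 3))
        model = lh.train_svr(X, np.full(8, 0.7))
        assert np.allclose(model.weights, 0, atol=1e-9)
        assert abs(model.bias - 0.7) <= SVR_EPSILON + 1e-9

    def test_weight_vector_length(self, rng):
        X = rng.random((10, 7))
        model = lh.train_svr(X, rng.random(10))
        assert model.weights.shape == (7,)

    def test_constant_features_warn(self):
        X = np.ones((5, 2))
        with pytest.warns(UserWarning, match="constant"):
            model = lh.train_svr(X, np.arange(5.0))
        assert np.allclose(model.weights, 0, atol=1e-9)


class TestLoocv:
    def test_planted_signal_recovered(self, rng):
        X = rng.random((20, 5))
        y = X @ np.array([2.0, -1.0, 0.0, 0.0, 1.0])
        pred, r = lh.loocv_accuracy(X, y)
        assert r > 0.95
        assert pred.shape == (20,)

    def test_permuted_labels_near_zero(self):
        rs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = rng.random((16, 4))
            y = rng.standard_normal(16)
            rs.append(lh.loocv_accuracy(X, y)[1])
        assert abs(np.mean(rs)) < 0.15

    def test_patient_order_invariance(self, rng):
        X = rng.random((12, 4))
        y = X @ np.array([1.0, 0.5, -0.5, 0.0]) + rng.normal(0, 0.05, 12)
        pred, r = lh.loocv_accuracy(X, y)
        perm = rng.permutation(12)
        pred_p, r_p = lh.loocv_accuracy(X[perm], y[perm])
        assert r_p == pytest.approx(r, abs=1e-9)
        assert np.allclose(pred_p, pred[perm], atol=1e-9)

    def test_too_few_patients(self, rng):
        with pytest.raises(DataError):
            lh.loocv_accuracy(rng.random((4, 3)), rng.random(4))


class TestPermutationSignificance:
    def test_pvalue_formula(self):
        nulls = np.linspace(-0.5, 0.4, 1000)
        assert _perm_pvalue(0.5, nulls) == pytest.approx(1 / 1001)
        assert _perm_pvalue(-0.9, nulls) == 1.0
        assert _perm_pvalue(0.0, nulls) == pytest.approx(
            (np.sum(nulls >= 0) + 1) / 1001
        )

    def test_strong_signal_significant(self, rng):
        X = rng.random((16, 4))
        y = X @ np.array([3.0, -2.0, 1.0, 0.5])
        p, r, nulls = lh.permutation_model_significance(X, y, n_perm=99, seed=0)
        assert p <= 0.05
        assert len(nulls) == 99
        assert 1 / 100 <= p <= 1.0

    def test_deterministic(self, rng):
        X = rng.random((10, 3))
        y = rng.random(10)
        a = lh.permutation_model_significance(X, y, n_perm=20, seed=5)
        b = lh.permutation_model_significance(X, y, n_perm=20, seed=5)
        assert a[0] == b[0]
        assert np.array_equal(a[2], b[2])


class TestFeatureWeightSignificance:
    def test_planted_effector_flagged(self, rng):
        X = rng.random((30, 6))
        y = 3.0 * X[:, 0] + rng.normal(0, 0.1, 30)
        table = lh.feature_weight_significance(X, y, n_perm=99, seed=0)
        assert bool(table["significant"].iloc[0])
        assert table["sign"].iloc[0] == 1

    def test_low_n_perm_warns(self, rng):
        X = rng.random((8, 3))
        with pytest.warns(UserWarning, match="resolution"):
            lh.feature_weight_significance(X, rng.random(8), n_perm=10, seed=0)

    def test_shared_shuffles_with_model_significance(self, rng):
        """Model P and weight nulls must come from one permutation stream."""
        lp = np.clip(rng.random((14, 5)) - 0.5, 0, None)
        feats = lh.assemble_features(make_patterns(lp))
        y = feats.X @ rng.normal(size=feats.X.shape[1]) + rng.normal(0, 0.1, 14)
        res = lh.fit_lesion_model(feats, y, "m", n_perm=50, seed=11)
        p, r, nulls = lh.permutation_model_significance(feats, y, n_perm=50, seed=11)
        table = lh.feature_weight_significance(feats, y, n_perm=50, seed=11)
        assert np.array_equal(res.null_accuracies, nulls)
        assert res.p_value == p
        assert np.array_equal(res.significant, table["significant"].to_numpy())
        assert np.allclose(res.weight_lo, table["null_p2.5"].to_numpy())


class TestClassifyLesionHubs:
    def _results(self, spec):
        """spec: feature -> {label: sign or 0 (not significant)}."""
        feats = sorted(spec)
        out = {}
        for label in ("net_locE", "net_gE", "sigma"):
            sig = [spec[f].get(label, 0) != 0 for f in feats]
            sign = [np.sign(spec[f].get(label, 0)) or 1 for f in feats]
            out[label] = make_result(feats, sig, sign, label)
        return out

    def test_integration_pattern(self):
        table = lh.classify_lesion_hubs(
            self._results({"a": {"net_locE": -1, "net_gE": 1, "sigma": -1}})
        )
        assert table.loc["a", "effect_class"] == "integration"

    def test_segregation_pattern(self):
        table = lh.classify_lesion_hubs(
            self._results({"a": {"net_locE": 1, "sigma": 1}})
        )
        assert table.loc["a", "effect_class"] == "segregation"

    def test_not_significant_absent(self):
        table = lh.classify_lesion_hubs(self._results({"a": {}, "b": {"sigma": -1}}))
        assert list(table.index) == ["b"]
        assert table.loc["b", "effect_class"] == "integration"

    def test_conflicting_pattern_unclassified(self):
        table = lh.classify_lesion_hubs(
            self._results({"a": {"net_locE": -1, "net_gE": -1}})
        )
        assert table.loc["a", "effect_class"] == "unclassified"

    def test_mismatched_feature_sets(self):
        res = self._results({"a": {"sigma": 1}})
        res["net_gE"] = make_result(["b"], [True], [1], "net_gE")
        with pytest.raises(DataError, match="feature set"):
            lh.classify_lesion_hubs(res)

    def test_missing_label_error(self):
        res = self._results({"a": {"sigma": 1}})
        del res["net_gE"]
        with pytest.raises(DataError):
            lh.classify_lesion_hubs(res)


class TestSplitHalf:
    def test_deterministic_and_two_results(self, rng):
        X = rng.random((14, 4))
        y = rng.random(14)
        a = lh.split_half_validation(X, y, n_perm=10, seed=3)
        b = lh.split_half_validation(X, y, n_perm=10, seed=3)
        assert len(a) == 2
        assert a[0].patient_ids == b[0].patient_ids
        assert abs(len(a[0].patient_ids) - len(a[1].patient_ids)) <= 1
        assert a[0].accuracy_r == b[0].accuracy_r

    def test_strong_signal_both_halves_significant(self, rng):
        X = rng.random((60, 8))
        w = rng.normal(size=8) * 2
        y = X @ w + rng.normal(0, 0.1, 60)
        r1, r2 = lh.split_half_validation(X, y, n_perm=99, seed=0)
        assert r1.p_value < 0.05 and r2.p_value < 0.05

    def test_too_few_patients(self, rng):
        with pytest.raises(DataError):
            lh.split_half_validation(rng.random((8, 3)), rng.random(8), seed=0)


class TestGroupTopologyComparison:
    def _curves(self, values):
        grid = np.round(np.arange(0.05, 0.4501, 0.01), 2)
        return [lh.MetricCurve(grid, v) for v in values]

    def test_identical_groups_nothing_significant(self, rng):
        vals = rng.random((6, 41)) * 0.1 + 0.5
        table = lh.group_topology_comparison(self._curves(vals), self._curves(vals))
        assert not table["significant"].any()

    def test_planted_reduction_detected(self, rng):
        base = 0.6 + rng.normal(0, 0.01, (20, 41))
        reduced = base[:10] - 0.05
        table = lh.group_topology_comparison(
            self._curves(reduced), self._curves(base[10:])
        )
        sig = table["significant"]
        assert sig.mean() > 0.9
        assert (table.loc[sig, "direction"] == "decrease").all()

    def test_bh_adjusted_not_below_raw(self, rng):
        a = rng.random((5, 41))
        b = rng.random((5, 41))
        table = lh.group_topology_comparison(self._curves(a), self._curves(b))
        assert np.all(table["p_fdr"].to_numpy() >= table["p"].to_numpy() - 1e-15)

    def test_small_group_error(self, rng):
        with pytest.raises(DataError):
            lh.group_topology_comparison(
                self._curves(rng.random((1, 41))), self._curves(rng.random((3, 41)))
            )

    def test_grid_mismatch_error(self, rng):
        a = self._curves(rng.random((3, 41)))
        other = [lh.MetricCurve(np.round(np.arange(0.06, 0.4601, 0.01), 2), v.values)
                 for v in self._curves(rng.random((3, 41)))]
        with pytest.raises(DataError, match="grid"):
            lh.group_topology_comparison(a, other)
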