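"""Hybrid classifier: OMP oracle checks, residual/distance fusion, CV protocol."""

import itertools

import numpy as np
import pytest
from scipy.stats import ortho_group

from ewtsleep import cross_validate, fit, merge_labels, omp, predict
from ewtsleep.classifier import (
    class_residuals,
    knn_class_distance,
    scheme_classes,
)


# ---------------------------------------------------------------- oracles
def best_subset_residual(D, y, k):
    """Exhaustive best-subset least squares over all supports of size <= k."""
    best = np.linalg.norm(y)
    for size in range(1, k + 1):
        for support in itertools.combinations(range(D.shape[1]), size):
            sub = D[:, support]
            sol, *_ = np.linalg.lstsq(sub, y, rcond=None)
            best = min(best, np.linalg.norm(y - sub @ sol))
    return best


def near_orthogonal_dictionary(rng, dim, n_atoms, jitter=1e-6):
    """Random orthonormal columns plus a small perturbation.

    For orthonormal atoms greedy OMP coincides with exhaustive best-subset
    selection; the jitter must stay small enough not to flip the selection
    order, otherwise the two can legitimately diverge.
    """
    Q = ortho_group.rvs(dim, random_state=rng)[:, :n_atoms]
    D = Q + jitter * rng.standard_normal((dim, n_atoms))
    return D


# ---------------------------------------------------------------- OMP
class TestOMP:
    def test_single_exact_atom(self):
        D = np.eye(4)[:, :2]
        coef = omp(D, 3 * D[:, 0], sparsity=1)
        np.testing.assert_allclose(coef, [3.0, 0.0], atol=1e-12)

    def test_exact_recovery_in_span(self, rng):
        D = np.eye(8)
        target = 2 * D[:, 1] - 5 * D[:, 6]
        coef = omp(D, target, sparsity=2)
        assert np.linalg.norm(target - D @ coef) < 1e-10

    def test_matches_best_subset_on_near_orthogonal(self, rng):
        for _ in range(30):
            D = near_orthogonal_dictionary(rng, 8, 8)
            y = rng.standard_normal(8)
            rho = int(rng.integers(1, 4))
            coef = omp(D, y, rho)
            got = np.linalg.norm(y - D @ coef)
            oracle = best_subset_residual(D, y, rho)
            assert got == pytest.approx(oracle, abs=1e-8)

    def test_matches_sklearn_omp(self, rng):
        """Independent route: sklearn's orthogonal_mp on unit-norm atoms."""
        from sklearn.linear_model import orthogonal_mp

        D = near_orthogonal_dictionary(rng, 12, 9)
        Dn = D / np.linalg.norm(D, axis=0)
        y = rng.standard_normal(12)
        ours = omp(Dn, y, sparsity=3)
        ref = orthogonal_mp(Dn, y, n_nonzero_coefs=3)
        assert np.linalg.norm(y - Dn @ ours) == pytest.approx(
            np.linalg.norm(y - Dn @ ref), abs=1e-10
        )

    def test_residual_nonincreasing_over_sparsity(self, rng):
        D = near_orthogonal_dictionary(rng, 10, 10)
        y = rng.standard_normal(10)
        res = [
            np.linalg.norm(y - D @ omp(D, y, s)) for s in range(1, 8)
        ]
        assert np.all(np.diff(res) <= 1e-12)

    def test_sparsity_bound_respected(self, rng):
        D = near_orthogonal_dictionary(rng, 10, 10)
        coef = omp(D, rng.standard_normal(10), sparsity=3)
        assert np.count_nonzero(coef) <= 3

    def test_zero_atom_rejected(self):
        D = np.zeros((4, 2))
        D[:, 1] = 1.0
        with pytest.raises(ValueError, match="zero-norm"):
            omp(D, np.ones(4), 1)


# ---------------------------------------------------------------- model
def toy_model(nn=1, rho=1):
    """Two orthogonal single-direction classes in 2-D, nn duplicates each."""
    X = np.array([[1.0, 0.0]] * max(nn, 1) + [[0.0, 1.0]] * max(nn, 1))
    y = ["a"] * max(nn, 1) + ["b"] * max(nn, 1)
    return fit(X, y, rho=rho, nn=nn, standardize=False)


class TestResidualsAndDistances:
    def test_self_representation_zero_residual(self):
        model = toy_model()
        target = np.array([1.0, 0.0])
        coef = omp(model.dictionary, target, model.rho)
        res = class_residuals(model, coef, target)
        assert res[0] == pytest.approx(0.0, abs=1e-12)
        assert res[1] == pytest.approx(1.0)

    def test_null_code_gives_target_norm(self):
        model = toy_model()
        target = np.array([3.0, 4.0])
        res = class_residuals(model, np.zeros(2), target)
        np.testing.assert_allclose(res, 5.0)

    def test_knn_median_hand_example(self):
        """Class rows at distances 1,2,3,4 from the target, nn=3 -> median 2."""
        X = np.array([[1.0], [2.0], [3.0], [4.0], [10.0], [11.0], [12.0]])
        y = ["a"] * 4 + ["b"] * 3
        model = fit(X, y, rho=1, nn=3, standardize=False)
        d = knn_class_distance(model, np.array([0.0]))
        assert d[0] == pytest.approx(2.0)
        assert d[1] == pytest.approx(11.0)

    def test_duplicate_rows_give_zero_distance(self):
        model = toy_model(nn=3)
        d = knn_class_distance(model, np.array([1.0, 0.0]))
        assert d[0] == 0.0


class TestPredict:
    def test_separable_orthogonal_classes(self, rng):
        model = toy_model(nn=1)
        X_te = np.array([[0.9, 0.1], [0.05, 1.2], [2.0, 0.0]])
        assert predict(model, X_te) == ["a", "b", "a"]

    def test_training_duplicate_scores_zero_total(self):
        model = toy_model(nn=3)
        labels, scores = predict(model, np.array([[1.0, 0.0]]), return_scores=True)
        assert labels == ["a"]
        assert scores[0].totals[model.classes.index("a")] == pytest.approx(0.0)

    def test_six_gaussian_clusters_high_accuracy(self, rng):
        """Well-separated clusters (means 5 sigma apart): near-perfect recovery."""
        n_tr, n_te, dim = 50, 10, 8
        means = 5.0 * np.eye(6, dim)
        X_tr, y_tr, X_te, y_te = [], [], [], []
        for e in range(6):
            X_tr.append(means[e] + rng.standard_normal((n_tr, dim)))
            X_te.append(means[e] + rng.standard_normal((n_te, dim)))
            y_tr += [f"c{e}"] * n_tr
            y_te += [f"c{e}"] * n_te
        model = fit(np.vstack(X_tr), y_tr, rho=20, nn=10)
        preds = predict(model, np.vstack(X_te))
        acc = np.mean([p == t for p, t in zip(preds, y_te)])
        assert acc >= 0.95

    def test_rotation_invariance(self, rng):
        """Rigid rotation of the feature space leaves predictions unchanged:
        Euclidean distances and least-squares residuals are equivariant."""
        dim = 6
        X = rng.standard_normal((40, dim)) + np.repeat(
            3 * np.eye(2, dim), 20, axis=0
        )
        y = ["a"] * 20 + ["b"] * 20
        X_te = rng.standard_normal((12, dim))
        R = ortho_group.rvs(dim, random_state=rng)
        m1 = fit(X, y, rho=5, nn=3, standardize=False)
        m2 = fit(X @ R.T, y, rho=5, nn=3, standardize=False)
        assert predict(m1, X_te) == predict(m2, X_te @ R.T)

    def test_rho_capped_with_warning(self):
        X = np.vstack([np.eye(2)] * 3)
        y = ["a", "b"] * 3
        with pytest.warns(UserWarning, match="capping"):
            model = fit(X, y, rho=100, nn=2)
        assert model.rho == 6

    def test_class_smaller_than_nn_rejected(self):
        X = np.eye(3)
        with pytest.raises(ValueError, match="fewer than nn"):
            fit(X, ["a", "a", "b"], rho=1, nn=2)


# ---------------------------------------------------------------- schemes / CV
class TestSchemes:
    def test_merge_wake_vs_sleep(self):
        stages = ["S0", "S1", "S2", "S3", "S4", "REM"]
        assert merge_labels(stages, "2class") == ["W"] + ["SLEEP"] * 5

    def test_merge_four_class(self):
        stages = ["S0", "S1", "S2", "S3", "S4", "REM"]
        assert merge_labels(stages, "4class") == ["W", "LS", "LS", "DS", "DS", "REM"]

    def test_five_class_merges_deep_stages(self):
        assert merge_labels(["S3", "S4"], "5class") == ["S3", "S3"]

    @pytest.mark.parametrize(
        "scheme, n", [("2class", 2), ("3class", 3), ("4class", 4),
                      ("5class", 5), ("6class", 6)]
    )
    def test_scheme_class_counts(self, scheme, n):
        assert len(scheme_classes(scheme)) == n


def clustered_features(rng, per_class=30, dim=8, sep=6.0):
    stages = ["S0", "S1", "S2", "S3", "S4", "REM"]
    X, y = [], []
    for e, s in enumerate(stages):
        X.append(sep * np.eye(6, dim)[e] + rng.standard_normal((per_class, dim)))
        y += [s] * per_class
    return np.vstack(X), y


class TestCrossValidate:
    def test_tenfold_sizes(self, rng):
        X, y = clustered_features(rng, per_class=20)
        res = cross_validate(X, y, scheme="6class", protocol="10fold",
                             rho=5, nn=3, seed=0)
        assert len(res.fold_reports) == 10
        for r in res.fold_reports:
            assert r.confusion_matrix.total == 12  # 120 instances / 10 folds

    def test_holdout_split_sizes(self, rng):
        X, y = clustered_features(rng, per_class=25)  # 150 instances
        res = cross_validate(X, y, scheme="6class", protocol="holdout",
                             rho=5, nn=3, seed=0)
        assert len(res.fold_reports) == 1
        assert res.fold_reports[0].confusion_matrix.total == 45  # 30%

    def test_same_seed_reproduces_metrics(self, rng):
        X, y = clustered_features(rng, per_class=20)
        r1 = cross_validate(X, y, rho=5, nn=3, seed=7)
        r2 = cross_validate(X, y, rho=5, nn=3, seed=7)
        assert r1.mean_accuracy == r2.mean_accuracy
        assert r1.mean_kappa == r2.mean_kappa

    def test_stratification_preserves_proportions(self, rng):
        X, y = clustered_features(rng, per_class=20)
        res = cross_validate(X, y, rho=5, nn=3, seed=1)
        for rep in res.fold_reports:
            row_sums = rep.confusion_matrix.counts.sum(axis=1)
            assert np.all(np.abs(row_sums - 2) <= 1)

    def test_separable_data_high_accuracy(self, rng):
        X, y = clustered_features(rng, per_class=20, sep=8.0)
        res = cross_validate(X, y, rho=10, nn=5, seed=3)
        assert res.mean_accuracy >= 95.0
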