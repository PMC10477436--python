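"""Canonical discriminant analysis against independent oracles.

The fitted CAN1 is checked against the closed-form Fisher discriminant
(two classes) and against a brute-force search over unit directions
maximising the one-way ANOVA F ratio (2-D, several classes); geometry
operations are checked by construction.
"""

import numpy as np
import pytest
from scipy import stats as sstats

from snapipe.cda import (
    CLASS_ORDER,
    FeatureMatrix,
    build_feature_matrix,
    centroid_geometry,
    dimension_test,
    distance_contraction,
    fit_cda,
    nearest_centroid_accuracy,
    split_feature_matrix,
)
from snapipe.errors import ArgumentError, InsufficientDataError
from snapipe.simulate import Labels
from snapipe.spectral import Spectrogram


def _two_gaussians(rng, n=200, p=5, shift=None):
    A = rng.normal(size=(p, p))
    L = np.linalg.cholesky(A @ A.T / p + np.eye(p))
    shift = np.zeros(p) if shift is None else shift
    X1 = rng.normal(size=(n, p)) @ L.T
    X2 = rng.normal(size=(n, p)) @ L.T + shift
    X = np.vstack([X1, X2])
    y = np.array(["a"] * n + ["b"] * n)
    return X, y, X1, X2


class TestFitAgainstOracles:
    def test_two_class_can1_matches_fisher_closed_form(self):
        rng = np.random.default_rng(0)
        shift = np.array([1.0, 0.5, 0.0, 0.0, -0.5])
        X, y, X1, X2 = _two_gaussians(rng, shift=shift)
        model = fit_cda(FeatureMatrix(X, y, np.arange(5), "linear"), k=1, pre_var=1.0)
        Sw = (X1 - X1.mean(0)).T @ (X1 - X1.mean(0)) + (X2 - X2.mean(0)).T @ (X2 - X2.mean(0))
        w = np.linalg.solve(Sw, X1.mean(0) - X2.mean(0))
        v = model.coefficients[:, 0]
        cosine = abs(w @ v) / (np.linalg.norm(w) * np.linalg.norm(v))
        assert cosine > 0.999

    def test_can1_matches_brute_force_f_maximising_direction_in_2d(self):
        rng = np.random.default_rng(1)
        means = [np.array([0.0, 0.0]), np.array([2.0, 1.0]), np.array([1.0, 3.0])]
        X = np.vstack([rng.normal(size=(80, 2)) + m for m in means])
        y = np.repeat(["a", "b", "c"], 80)
        model = fit_cda(FeatureMatrix(X, y, np.arange(2), "linear"), k=1, pre_var=1.0)

        def f_ratio(theta):
            d = np.array([np.cos(theta), np.sin(theta)])
            proj = X @ d
            return sstats.f_oneway(*(proj[y == c] for c in "abc")).statistic

        thetas = np.linspace(0.0, np.pi, 3600, endpoint=False)
        best = thetas[int(np.argmax([f_ratio(t) for t in thetas]))]
        v = model.coefficients[:, 0]
        angle = np.arccos(
            np.clip(abs(np.array([np.cos(best), np.sin(best)]) @ v) / np.linalg.norm(v), 0, 1)
        )
        assert np.degrees(angle) < 1.0

    def test_identical_classes_have_near_null_leading_eigenvalue(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 6))
        y = np.repeat(["a", "b"], 200)
        model = fit_cda(FeatureMatrix(X, y, np.arange(6), "linear"), k=1, pre_var=1.0)
        # simulated null quantile of the leading eigenvalue
        null = []
        for rep in range(200):
            perm = rng.permutation(y)
            null.append(
                fit_cda(FeatureMatrix(X, perm, np.arange(6), "linear"), k=1, pre_var=1.0).eigenvalues[0]
            )
        assert model.eigenvalues[0] < np.quantile(null, 0.99)

    def test_collinear_class_means_give_rank_one_between_scatter(self):
        rng = np.random.default_rng(3)
        direction = np.array([1.0, 2.0, -1.0])
        X = np.vstack([rng.normal(size=(100, 3)) + c * direction for c in (0.0, 3.0, 6.0)])
        y = np.repeat(["a", "b", "c"], 100)
        model = fit_cda(FeatureMatrix(X, y, np.arange(3), "linear"), k=2, pre_var=1.0)
        assert model.eigenvalues_all[1] < 0.05 * model.eigenvalues_all[0]


class TestModelInvariants:
    def test_eigenvalues_nonnegative_and_nonincreasing(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(size=(60, 8)) + m for m in (0, 1, 2, 3)])
        y = np.repeat(list("abcd"), 60)
        model = fit_cda(FeatureMatrix(X, y, np.arange(8), "linear"), k=3, pre_var=1.0)
        lam = model.eigenvalues_all
        assert np.all(lam >= 0)
        assert np.all(np.diff(lam) <= 1e-12)

    def test_scores_have_identity_within_class_covariance(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(size=(100, 6)) + m for m in (0, 2, 4)])
        y = np.repeat(list("abc"), 100)
        model = fit_cda(FeatureMatrix(X, y, np.arange(6), "linear"), k=2, pre_var=1.0)
        centered = np.vstack(
            [model.scores[y == c] - model.scores[y == c].mean(0) for c in "abc"]
        )
        pooled = centered.T @ centered / (len(y) - 3)
        np.testing.assert_allclose(pooled, np.eye(2), atol=1e-6)

    def test_trial_permutation_leaves_eigenvalues_unchanged(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(size=(50, 4)) + m for m in (0, 1.5)])
        y = np.repeat(["a", "b"], 50)
        model1 = fit_cda(FeatureMatrix(X, y, np.arange(4), "linear"), pre_var=1.0)
        perm = rng.permutation(len(y))
        model2 = fit_cda(FeatureMatrix(X[perm], y[perm], np.arange(4), "linear"), pre_var=1.0)
        np.testing.assert_allclose(model1.eigenvalues_all, model2.eigenvalues_all, atol=1e-10)

    def test_k_above_class_limit_truncates_with_warning(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(size=(30, 4)), rng.normal(size=(30, 4)) + 1])
        y = np.repeat(["a", "b"], 30)
        with pytest.warns(RuntimeWarning, match="truncating"):
            model = fit_cda(FeatureMatrix(X, y, np.arange(4), "linear"), k=3, pre_var=1.0)
        assert model.k == 1


class TestDimensionTest:
    def test_strong_separation_flags_first_dimension(self):
        rng = np.random.default_rng(8)
        for rep in range(20):
            X = np.vstack([rng.normal(size=(40, 5)), rng.normal(size=(40, 5)) + 5.0])
            y = np.repeat(["a", "b"], 40)
            model = fit_cda(FeatureMatrix(X, y, np.arange(5), "linear"), pre_var=1.0)
            table = dimension_test(model)
            assert bool(table.significant.iloc[0])

    def test_null_classes_rarely_significant(self):
        rng = np.random.default_rng(9)
        hits = 0
        reps = 40
        for rep in range(reps):
            X = rng.normal(size=(120, 5))
            y = np.repeat(["a", "b", "c"], 40)
            model = fit_cda(FeatureMatrix(X, y, np.arange(5), "linear"), pre_var=1.0)
            hits += int(dimension_test(model).significant.any())
        assert hits / reps <= 0.10 + 0.10  # alpha plus simulation slack at 40 reps

    def test_single_class_rejected_at_feature_matrix(self):
        with pytest.raises(InsufficientDataError):
            FeatureMatrix(np.zeros((10, 3)), np.repeat("a", 10), np.arange(3), "linear")


class TestGeometry:
    def _toy_model(self, shift=3.0, seed=10):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(size=(100, 4)), rng.normal(size=(100, 4)) + shift])
        y = np.repeat(["a", "b"], 100)
        return fit_cda(FeatureMatrix(X, y, np.arange(4), "linear"), k=1, pre_var=1.0)

    def test_distance_matrix_symmetric_zero_diagonal(self):
        geom = centroid_geometry(self._toy_model())
        D = geom.distance_matrix
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)

    def test_duplicated_class_has_near_zero_distance(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(200, 4))
        X = np.vstack([base[:100], base[100:]])
        y = np.repeat(["a", "b"], 100)
        model = fit_cda(FeatureMatrix(X, y, np.arange(4), "linear"), k=1, pre_var=1.0)
        geom = centroid_geometry(model)
        # same-distribution split: centroid distance is sampling noise only
        assert geom.distance_matrix[0, 1] < 0.5

    def test_two_class_distance_equals_score_mean_gap(self):
        model = self._toy_model()
        geom = centroid_geometry(model)
        gap = abs(
            model.scores[model.labels == "a"].mean() - model.scores[model.labels == "b"].mean()
        )
        assert geom.distance_matrix[0, 1] == pytest.approx(gap, abs=1e-6)


class TestDistanceContraction:
    def _geom(self, scale=1.0, seed=12):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(size=(60, 3)) + m for m in (0.0, 4.0, 8.0)])
        y = np.repeat(list("abc"), 60)
        model = fit_cda(FeatureMatrix(X, y, np.arange(3), "linear"), k=2, pre_var=1.0)
        geom = centroid_geometry(model)
        geom.centroids *= scale
        geom.distance_matrix *= scale
        return geom

    def test_identical_geometries_give_unit_ratios(self):
        g = self._geom()
        contr = distance_contraction(g, g)
        off = contr.ratio_matrix[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_tenfold_shrink_gives_tenfold_ratios(self):
        contr = distance_contraction(self._geom(1.0), self._geom(0.1))
        off = contr.ratio_matrix[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 10.0, rtol=1e-6)
        assert contr.max_ratio == pytest.approx(10.0, rel=1e-6)

    def test_zero_bic_distance_reported_infinite_with_flag(self):
        contr = distance_contraction(self._geom(1.0), self._geom(0.0))
        assert contr.has_infinite
        assert np.isinf(contr.max_ratio)


class TestFeatureMatrixConstruction:
    def _spectrograms(self):
        rng = np.random.default_rng(13)
        freqs = np.linspace(0, 20, 41)
        sgs = []
        for group in ("CTRL", "2K1C", "2K1C_LOS"):
            for nerve in ("renal", "splanchnic"):
                for animal in (1, 2):
                    power = np.abs(rng.normal(size=(5, 41))) + 0.1
                    lab = Labels(group, nerve, "BAS", animal)
                    sgs.append(Spectrogram(power, freqs, np.arange(5.0), lab, "envelope"))
        return sgs

    def test_six_composite_classes(self):
        fm = build_feature_matrix(self._spectrograms(), "envelope", (0.0, 10.0))
        assert fm.classes == list(CLASS_ORDER)

    def test_row_count_is_windows_times_recordings(self):
        fm = build_feature_matrix(self._spectrograms(), "envelope", (0.0, 10.0))
        assert fm.X.shape[0] == 6 * 2 * 5

    def test_log_transform_of_unit_spectra_is_zero(self, labels):
        sgs = self._spectrograms()
        for sg in sgs:
            sg.power = np.ones_like(sg.power)
        fm = build_feature_matrix(sgs, "envelope", (0.0, 10.0), transform="log10")
        assert not fm.X.any()

    def test_window_holdout_split_partitions_rows(self):
        fm = build_feature_matrix(self._spectrograms(), "envelope", (0.0, 10.0))
        train, X_test, y_test = split_feature_matrix(fm, "windows", fraction=0.2)
        assert train.X.shape[0] + len(X_test) == fm.X.shape[0]
        assert set(np.unique(y_test)) == set(CLASS_ORDER)

    def test_animal_holdout_removes_one_animal_per_class(self):
        fm = build_feature_matrix(self._spectrograms(), "envelope", (0.0, 10.0))
        train, X_test, y_test = split_feature_matrix(fm, "animals")
        assert 2 not in train.animal_ids
        assert len(X_test) == 6 * 5
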