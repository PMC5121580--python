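"""Discriminant scores, classification and confusion-table metrics."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dartlda import (
    class_metrics,
    classify,
    discriminant_scores,
    fit_lda,
    ner_percent,
)
from dartlda.lda import LDAModel, make_positive_definite


def _toy_two_class():
    X = np.array([[0.0], [2.0], [4.0], [6.0]])
    y = ["A", "A", "B", "B"]
    return X, y


def brute_force_discriminants(X, centroids, pooled, priors):
    """Direct evaluation with an explicitly inverted pooled covariance."""
    inv = np.linalg.inv(pooled)
    log_det = np.log(np.linalg.det(pooled))
    D = np.empty((X.shape[0], centroids.shape[0]))
    for g, c in enumerate(centroids):
        d = X - c
        D[:, g] = np.einsum("ij,jk,ik->i", d, inv, d) + log_det - 2 * np.log(priors[g])
    return D


class TestFit:
    def test_centroids_at_class_means(self):
        rng = np.random.default_rng(0)
        a = np.array([1.0, 2.0]) + rng.normal(0, 1e-6, size=(5, 2))
        b = np.array([5.0, -1.0]) + rng.normal(0, 1e-6, size=(5, 2))
        model = fit_lda(np.vstack([a, b]), ["a"] * 5 + ["b"] * 5)
        np.testing.assert_allclose(model.centroids[0], [1.0, 2.0], atol=1e-5)
        np.testing.assert_allclose(model.centroids[1], [5.0, -1.0], atol=1e-5)

    def test_default_priors_equal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(9, 2))
        model = fit_lda(X, ["a", "b", "c"] * 3)
        np.testing.assert_allclose(model.priors, [1 / 3] * 3)

    def test_pooled_variance_hand_computed_one_dimensional(self):
        # class A {0, 2}: var 2; class B {4, 6}: var 2; pooled = (2+2)/(4-2) = 2
        X, y = _toy_two_class()
        model = fit_lda(X, y)
        assert model.pooled_covariance[0, 0] == pytest.approx(2.0)

    def test_rejects_single_sample_class_and_single_class(self):
        with pytest.raises(ValueError):
            fit_lda(np.array([[0.0], [1.0], [2.0]]), ["a", "a", "b"])
        with pytest.raises(ValueError):
            fit_lda(np.array([[0.0], [1.0]]), ["a", "a"])

    def test_singular_pooled_covariance_repaired_by_ridge(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        model = fit_lda(X, ["a", "a", "b", "b"])  # zero within-class scatter
        assert np.all(np.isfinite(model.pooled_covariance))
        pred = classify(model, np.array([[0.01, 0.01], [0.99, 0.99]]))
        assert list(pred) == ["a", "b"]

    def test_make_positive_definite_leaves_pd_untouched(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        out, _ = make_positive_definite(S)
        np.testing.assert_array_equal(out, S)


class TestDiscriminantScores:
    def _identity_model(self, centroids, priors=None):
        centroids = np.asarray(centroids, dtype=float)
        g, k = centroids.shape
        priors = np.full(g, 1 / g) if priors is None else np.asarray(priors)
        return LDAModel(
            None,
            np.array([f"c{i}" for i in range(g)]),
            centroids,
            np.eye(k),
            0.0,
            priors,
        )

    def test_score_at_centroid_is_prior_penalty_only(self):
        model = self._identity_model(np.zeros((3, 2)) + np.arange(3)[:, None] * 10)
        D = discriminant_scores(model, model.centroids[0])
        assert D[0] == pytest.approx(2 * np.log(3), abs=1e-12)  # ≈ 2.1972

    def test_symmetric_midpoint_ties(self):
        model = self._identity_model([[0.0, 0.0], [2.0, 0.0]])
        D = discriminant_scores(model, np.array([1.0, 0.0]))
        assert D[0] == pytest.approx(D[1])

    def test_hand_evaluated_two_class_scores(self):
        model = self._identity_model([[0.0, 0.0], [2.0, 0.0]])
        D = discriminant_scores(model, np.array([0.5, 0.0]))
        assert D[0] == pytest.approx(0.25 + 2 * np.log(2), abs=1e-9)  # ≈ 1.636
        assert D[1] == pytest.approx(2.25 + 2 * np.log(2), abs=1e-9)  # ≈ 3.636

    def test_dimension_mismatch_rejected(self):
        model = self._identity_model([[0.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="mismatch"):
            discriminant_scores(model, np.array([1.0]))


class TestClassify:
    def test_sample_at_centroid_gets_that_class(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(5, 0.1, (5, 2))])
        y = ["a"] * 5 + ["b"] * 5
        model = fit_lda(X, y)
        assert classify(model, model.centroids[0][None, :])[0] == "a"

    def test_tie_broken_by_first_listed_class(self):
        model = TestDiscriminantScores()._identity_model([[0.0], [2.0]])
        assert classify(model, np.array([[1.0]]))[0] == "c0"

    def test_matches_brute_force_evaluation_on_random_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            g = rng.integers(2, 4)
            k = rng.integers(1, 4)
            n_per = rng.integers(3, 11)
            X = np.vstack(
                [rng.normal(3 * i, 1.0, size=(n_per, k)) for i in range(g)]
            )
            y = np.repeat([f"c{i}" for i in range(g)], n_per)
            model = fit_lda(X, y)
            D = discriminant_scores(model, X)
            D_oracle = brute_force_discriminants(
                X, model.centroids, model.pooled_covariance, model.priors
            )
            np.testing.assert_allclose(D, D_oracle, atol=1e-8)
            np.testing.assert_array_equal(
                classify(model, X), model.class_labels[np.argmin(D_oracle, axis=1)]
            )

    def test_agrees_with_sklearn_reference(self):
        from sklearn import discriminant_analysis as sklearn_lda

        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(i * 2, 1.0, size=(15, 3)) for i in range(3)])
        y = np.repeat(["a", "b", "c"], 15)
        model = fit_lda(X, y)
        ref = sklearn_lda.LinearDiscriminantAnalysis(
            solver="lsqr", priors=[1 / 3] * 3
        ).fit(X, y)
        assert np.mean(classify(model, X) == ref.predict(X)) == 1.0

    def test_unequal_priors_shift_boundary_toward_low_prior_class(self):
        X, y = _toy_two_class()
        equal = fit_lda(X, y)
        skewed = fit_lda(X, y, priors={"A": 0.9, "B": 0.1})
        grid = np.linspace(0.0, 6.0, 2001)[:, None]
        boundary_equal = grid[classify(equal, grid) == "B"][0, 0]
        boundary_skewed = grid[classify(skewed, grid) == "B"][0, 0]
        assert boundary_equal == pytest.approx(3.0, abs=0.01)
        assert boundary_skewed > boundary_equal  # B shrinks under low prior

    @given(st.floats(min_value=-1e3, max_value=1e3, allow_nan=False))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_constant_shift_of_scores_never_changes_assignment(self, shift):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 1, (6, 2)), rng.normal(4, 1, (6, 2))])
        y = ["a"] * 6 + ["b"] * 6
        model = fit_lda(X, y)
        D = discriminant_scores(model, X)
        pred_shifted = model.class_labels[np.argmin(D + shift, axis=1)]
        np.testing.assert_array_equal(classify(model, X), pred_shifted)


class TestMetrics:
    def test_ner_examples(self):
        assert ner_percent(["a", "b"], ["a", "b"]) == 100.0
        y = ["a"] * 14
        p = ["a"] * 12 + ["b"] * 2
        assert ner_percent(y, p) == pytest.approx(100 * 12 / 14)  # 85.71%
        assert ner_percent(["a", "a"], ["b", "b"]) == 0.0
        with pytest.raises(ValueError):
            ner_percent([], [])

    def test_perfect_assignment_gives_100_everywhere(self):
        y = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        m = class_metrics(y, y)
        np.testing.assert_array_equal(m.specificity, 100.0)
        np.testing.assert_array_equal(m.selectivity, 100.0)
        assert m.ner == 100.0

    def test_all_predicted_one_class(self):
        y = ["A", "A", "B", "B"]
        p = ["A", "A", "A", "A"]
        m = class_metrics(y, p)
        a = list(m.classes).index("A")
        b = list(m.classes).index("B")
        assert m.specificity[a] == 0.0  # every B wrongly assigned to A
        assert m.selectivity[b] == 100.0  # vacuous precision convention

    def test_unknown_predicted_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            class_metrics(["a", "b"], ["a", "z"])
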