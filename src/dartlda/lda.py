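"""Bayesian linear discriminant classification.

Each class g is a multivariate Gaussian sharing one pooled covariance S_p;
an object x is assigned to the class minimizing the discriminant score

    D(g|x) = (x − c_g)ᵀ S_p⁻¹ (x − c_g) + ln|S_p| − 2 ln P_g

where c_g is the class centroid, S_p the pooled within-class covariance and
P_g the prior probability (equal for all classes by default).  The pooled
covariance is the (n_g − 1)-weighted average of per-class covariances.

Classification quality is summarized by the non-error rate (NER%, the
percentage of overall correct assignments) and per-class specificity
(TN/(TN+FP)) and selectivity (precision, TP/(TP+FP); 100 by convention when
nothing is assigned to the class).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky

__all__ = [
    "LDAModel",
    "ClassMetrics",
    "fit_lda",
    "discriminant_scores",
    "classify",
    "ner_percent",
    "class_metrics",
]


def make_positive_definite(S: np.ndarray, eps0: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Return (S_pd, upper Cholesky factor), adding ridge ε·tr(S)/K·I if needed.

    ε starts at ``eps0`` and escalates by decades until the Cholesky
    factorization succeeds; resampled training sets can drop rank, which this
    repairs without visibly perturbing well-conditioned fits.
    """
    S = np.asarray(S, dtype=float)
    k = S.shape[0]
    try:
        return S, cholesky(S, lower=False)
    except np.linalg.LinAlgError:
        pass
    base = np.trace(S) / k
    if base <= 0:
        base = 1.0
    eps = eps0
    while eps <= 1.0:
        S_r = S + eps * base * np.eye(k)
        try:
            return S_r, cholesky(S_r, lower=False)
        except np.linalg.LinAlgError:
            eps *= 10.0
    raise np.linalg.LinAlgError("covariance not repairable by ridge escalation")


def _fit_arrays(
    X: np.ndarray, codes: np.ndarray, n_classes: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Class centroids, pooled covariance, its Cholesky factor and log-det."""
    n, k = X.shape
    centroids = np.empty((n_classes, k))
    scatter = np.zeros((k, k))
    for g in range(n_classes):
        Xg = X[codes == g]
        if Xg.shape[0] < 2:
            raise ValueError(f"class {g} has fewer than 2 samples")
        mu = Xg.mean(axis=0)
        centroids[g] = mu
        d = Xg - mu
        scatter += d.T @ d
    pooled = scatter / (n - n_classes)
    pooled, chol = make_positive_definite(pooled)
    log_det = 2.0 * float(np.log(np.diag(chol)).sum())
    return centroids, pooled, chol, log_det


def _discriminant_matrix(
    X: np.ndarray,
    centroids: np.ndarray,
    chol: np.ndarray,
    log_det: float,
    log_priors: np.ndarray,
) -> np.ndarray:
    """(M, G) matrix of D(g|x) for each row of X."""
    m = X.shape[0]
    G = centroids.shape[0]
    D = np.empty((m, G))
    for g in range(G):
        d = X - centroids[g]
        z = cho_solve((chol, False), d.T)
        D[:, g] = np.einsum("ij,ji->i", d, z) + log_det - 2.0 * log_priors[g]
    return D


@dataclass
class LDAModel:
    """Fitted pooled-covariance discriminant model over a feature subset."""

    feature_indices: np.ndarray | None  # column subset of the score matrix, or None
    class_labels: np.ndarray  # (G,)
    centroids: np.ndarray  # (G, K)
    pooled_covariance: np.ndarray  # (K, K)
    log_det: float
    priors: np.ndarray  # (G,), positive, sum 1
    _chol: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.centroids.shape[1]


def fit_lda(
    scores: np.ndarray,
    labels: Sequence[str],
    feature_indices: Sequence[int] | None = None,
    priors: Mapping[str, float] | Sequence[float] | None = None,
) -> LDAModel:
    """Fit the pooled-covariance Bayesian discriminant model.

    Parameters
    ----------
    scores : (N, K_all) array
        Sample coordinates (typically PCA scores).
    labels : sequence of str
        Class label per sample; ≥ 2 classes, each with ≥ 2 samples.
    feature_indices : sequence of int, optional
        Column subset to train on (e.g. forward-selected PCs).  When given,
        the model remembers it and prediction accepts either the full score
        matrix or the already-subset columns.
    priors : mapping or sequence, optional
        Class priors; default equal for all classes.  Normalized to sum 1.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    fi = None
    if feature_indices is not None:
        fi = np.asarray(list(feature_indices), dtype=int)
        if fi.size == 0:
            raise ValueError("feature_indices must be nonempty")
        X = X[:, fi]
    labels = np.asarray(labels)
    classes, codes = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    centroids, pooled, chol, log_det = _fit_arrays(X, codes, classes.size)

    if priors is None:
        pr = np.full(classes.size, 1.0 / classes.size)
    elif isinstance(priors, Mapping):
        pr = np.asarray([priors[c] for c in classes], dtype=float)
    else:
        pr = np.asarray(priors, dtype=float)
    if pr.size != classes.size or np.any(pr <= 0):
        raise ValueError("priors must be positive, one per class")
    pr = pr / pr.sum()

    return LDAModel(fi, classes, centroids, pooled, log_det, pr, chol)


def _model_features(model: LDAModel, x: np.ndarray) -> np.ndarray:
    X = np.asarray(x, dtype=float)
    one_d = X.ndim == 1
    if one_d:
        X = X[None, :]
    k = model.n_features
    if X.shape[1] == k:
        pass
    elif model.feature_indices is not None and X.shape[1] > k:
        X = X[:, model.feature_indices]
    else:
        raise ValueError(f"feature dimension mismatch: expected {k}, got {X.shape[1]}")
    return X if not one_d else X  # caller squeezes


def discriminant_scores(model: LDAModel, x: np.ndarray) -> np.ndarray:
    """Per-class discriminant scores D(g|x); lower is better.

    ``x`` may be a single sample (1-D) or a stack of rows; full-width score
    rows are subset to the model's selected features automatically.
    """
    one_d = np.asarray(x).ndim == 1
    X = _model_features(model, x)
    chol = model._chol
    if chol is None:
        _, chol = make_positive_definite(model.pooled_covariance)
    D = _discriminant_matrix(X, model.centroids, chol, model.log_det, np.log(model.priors))
    return D[0] if one_d else D


def classify(model: LDAModel, score_rows: np.ndarray) -> np.ndarray:
    """Assign each row to the class with minimal discriminant score.

    Ties are broken in favor of the first class in ``model.class_labels``
    (``argmin`` returns the first minimizer).
    """
    D = discriminant_scores(model, score_rows)
    D = np.atleast_2d(D)
    return model.class_labels[np.argmin(D, axis=1)]


def ner_percent(true_labels: Sequence, predicted_labels: Sequence) -> float:
    """Non-error rate: 100 × (number of correct assignments) / N."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0:
        raise ValueError("cannot compute NER of an empty set")
    if t.shape != p.shape:
        raise ValueError("true and predicted label arrays differ in length")
    return float(100.0 * np.mean(t == p))


@dataclass
class ClassMetrics:
    """Per-class specificity/selectivity (%) and overall NER%."""

    classes: np.ndarray
    specificity: np.ndarray  # TN / (TN + FP) × 100
    selectivity: np.ndarray  # precision: TP / (TP + FP) × 100; 100 if no predictions
    ner: float

    def as_dict(self) -> dict:
        return {
            "ner_percent": self.ner,
            "per_class": {
                str(c): {"specificity": float(sp), "selectivity": float(se)}
                for c, sp, se in zip(self.classes, self.specificity, self.selectivity)
            },
        }


def class_metrics(true_labels: Sequence, predicted_labels: Sequence) -> ClassMetrics:
    """Confusion-table metrics per class plus overall NER%."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0 or t.shape != p.shape:
        raise ValueError("labels must be nonempty and of equal length")
    classes = np.unique(t)
    unknown = np.setdiff1d(np.unique(p), classes)
    if unknown.size:
        raise ValueError(f"predictions contain unknown labels: {list(unknown)}")
    spec = np.empty(classes.size)
    sel = np.empty(classes.size)
    for i, c in enumerate(classes):
        tp = np.sum((t == c) & (p == c))
        fp = np.sum((t != c) & (p == c))
        tn = np.sum((t != c) & (p != c))
        spec[i] = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else 100.0
        sel[i] = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else 100.0
    return ClassMetrics(classes, spec, sel, ner_percent(t, p))
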