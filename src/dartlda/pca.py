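"""Principal component analysis with held-out reprojection.

PCA serves as the dimensionality-reduction stage ahead of discriminant
analysis: the scaled sample × m/z matrix is mean-centered and decomposed by
SVD; scores are the sample coordinates on the components, loadings the
weights of the original m/z variables.  Held-out samples are reprojected
with the training offsets and loadings (never refit), which is what makes
the downstream validation leakage-free.

Sign convention: each loading column is oriented so its largest-magnitude
entry is positive, making loadings (and hence marker back-projection)
reproducible across runs and BLAS builds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import AlignedMatrix

__all__ = ["PCAModel", "fit_pca", "project", "explained_variance_report"]


@dataclass
class PCAModel:
    """Fitted PCA: training offsets, orthonormal loadings, variance shares."""

    column_means: np.ndarray  # (P,)
    loadings: np.ndarray  # (P, K), orthonormal columns
    explained_variance_pct: np.ndarray  # (K,), nonincreasing, 0-100 scale
    training_scores: np.ndarray  # (N, K)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _as_array(m: AlignedMatrix | np.ndarray) -> np.ndarray:
    X = m.X if isinstance(m, AlignedMatrix) else np.asarray(m, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D sample × variable matrix")
    return X


def fit_pca(m: AlignedMatrix | np.ndarray, n_components: int) -> PCAModel:
    """Mean-centered SVD-based PCA.

    Parameters
    ----------
    m : AlignedMatrix or ndarray
        Scaled data, N samples × P variables, N ≥ 2.
    n_components : int
        Number of components K, 1 ≤ K ≤ min(N−1, P).
    """
    X = _as_array(m)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    k_max = min(n - 1, p)
    if not 1 <= n_components <= k_max:
        raise ValueError(f"n_components must be in [1, {k_max}], got {n_components}")

    means = X.mean(axis=0)
    Xc = X - means
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    if total <= 0:
        raise ValueError("matrix has zero total variance")
    pct = var / total * 100.0

    loadings = vt[:n_components].T.copy()
    # deterministic orientation: largest-|entry| per component positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    loadings *= flip
    scores = Xc @ loadings
    return PCAModel(means, loadings, pct[:n_components], scores)


def project(model: PCAModel, m: AlignedMatrix | np.ndarray) -> np.ndarray:
    """Reproject samples into the fitted PC space: (X − means) · loadings.

    The input must already carry the training scaling (per-sample row scaling
    plus the training column min/max).
    """
    X = _as_array(m)
    if X.shape[1] != model.column_means.size:
        raise ValueError(
            f"column mismatch: model has {model.column_means.size} variables, "
            f"input has {X.shape[1]}"
        )
    return (X - model.column_means) @ model.loadings


def explained_variance_report(model: PCAModel) -> list[tuple[int, float]]:
    """(PC number, explained variance %) pairs, PC numbers 1-based."""
    return [(i + 1, float(v)) for i, v in enumerate(model.explained_variance_pct)]
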