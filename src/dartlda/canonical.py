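"""Canonical discriminant analysis and m/z marker extraction.

Canonical roots are the directions in the selected-PC space that maximize
the ratio of between-class to within-class variance; with G classes at most
G − 1 roots exist.  Because the PCs are linear combinations of the original
m/z variables, the root coefficients can be propagated back through the PCA
loadings to per-m/z *marker weights*: the signed contribution of every m/z
signal to each discriminant root.  Large-magnitude weights identify the
spectral markers driving the class separation.

Root coefficient vectors are normalized to unit Euclidean norm and oriented
so their largest-magnitude entry is positive; since the PCA loadings have
orthonormal columns, the back-projected weight vector of each root is then
also unit-norm, which is what makes fixed absolute thresholds (0.1 on root
1, 0.05 on root 2 by default) meaningful.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import norm

from .lda import make_positive_definite

__all__ = [
    "CanonicalModel",
    "canonical_analysis",
    "variable_weights",
    "significant_weights",
    "marker_table",
    "interpret_roots",
    "isolating_root",
]


@dataclass
class CanonicalModel:
    """Canonical roots over the selected-PC score space."""

    root_coefficients: np.ndarray  # (K_sel, R), unit-norm columns
    root_scores: np.ndarray  # (N, R)
    eigenvalues: np.ndarray  # (R,), between/within variance ratios, nonincreasing
    grand_mean: np.ndarray  # (K_sel,)
    class_labels: np.ndarray  # (G,)

    @property
    def n_roots(self) -> int:
        return self.root_coefficients.shape[1]


def canonical_analysis(scores: np.ndarray, labels: Sequence) -> CanonicalModel:
    """Eigen-decomposition of (within scatter)⁻¹ × (between scatter).

    Parameters
    ----------
    scores : (N, K_sel) array
        Sample coordinates on the selected PCs (the final LDA model's
        features).
    labels : sequence
        Class label per sample; at least 2 classes.

    Roots are ordered by decreasing eigenvalue (between/within variance
    ratio).  Root scores are the mean-centered scores projected on the
    coefficient vectors.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    classes, codes = np.unique(labels, return_inverse=True)
    G = classes.size
    if G < 2:
        raise ValueError("canonical analysis requires at least 2 classes")
    n, k = X.shape
    grand = X.mean(axis=0)

    Sw = np.zeros((k, k))
    Sb = np.zeros((k, k))
    for g in range(G):
        Xg = X[codes == g]
        mu = Xg.mean(axis=0)
        d = Xg - mu
        Sw += d.T @ d
        dm = (mu - grand)[:, None]
        Sb += Xg.shape[0] * (dm @ dm.T)
    Sw, _ = make_positive_definite(Sw)

    vals, vecs = eigh(Sb, Sw)  # ascending
    r = min(G - 1, k)
    vals = vals[::-1][:r]
    vecs = vecs[:, ::-1][:, :r]
    vals = np.clip(vals, 0.0, None)

    norms = np.linalg.norm(vecs, axis=0)
    norms[norms == 0] = 1.0
    vecs = vecs / norms
    flip = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(r)])
    flip[flip == 0] = 1.0
    vecs = vecs * flip

    root_scores = (X - grand) @ vecs
    return CanonicalModel(vecs, root_scores, vals, grand, classes)


def variable_weights(
    pca_loadings: np.ndarray, root_coefficients: np.ndarray
) -> np.ndarray:
    """Back-project root coefficients through PCA loadings to m/z weights.

    weight[j, r] = Σ_k loading[j, k] · coefficient[k, r] over the selected
    PCs k — the contribution of original variable j to canonical root r.
    """
    L = np.asarray(pca_loadings, dtype=float)
    C = np.asarray(root_coefficients, dtype=float)
    if L.ndim != 2 or C.ndim != 2 or L.shape[1] != C.shape[0]:
        raise ValueError(
            f"shape mismatch: loadings {L.shape} vs coefficients {C.shape}"
        )
    return L @ C


def significant_weights(
    weights: np.ndarray,
    method: str = "fixed",
    thresholds: Sequence[float] = (0.1, 0.05),
    deviation_multiplier: float = 4.0,
) -> np.ndarray:
    """Boolean significance flags per (variable, root).

    ``method="fixed"``: flag |weight| > thresholds[r] on root r (defaults
    0.1 on root 1 and 0.05 on root 2, the usual normal-probability-plot
    reading for these models).

    ``method="normal_probability"``: operational automatic mode — per root,
    the ordered weights are regressed on normal quantiles and variables whose
    residual from that straight line exceeds ``deviation_multiplier`` times
    the residual standard deviation are flagged (a weight population that is
    one normal distribution flags essentially nothing).
    """
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    if W.shape[0] == 1 and np.asarray(weights).ndim == 1:
        W = W.T
    p, r = W.shape
    flags = np.zeros((p, r), dtype=bool)
    if method == "fixed":
        if len(thresholds) < r:
            raise ValueError(f"need {r} thresholds, got {len(thresholds)}")
        for j in range(r):
            flags[:, j] = np.abs(W[:, j]) > thresholds[j]
    elif method == "normal_probability":
        if p < 4:
            raise ValueError("normal-probability mode needs at least 4 variables")
        ranks = np.arange(1, p + 1)
        q = norm.ppf((ranks - 0.375) / (p + 0.25))
        for j in range(r):
            order = np.argsort(W[:, j])
            w_sorted = W[order, j]
            A = np.column_stack([np.ones(p), q])
            coef, *_ = np.linalg.lstsq(A, w_sorted, rcond=None)
            resid = w_sorted - A @ coef
            sd = resid.std(ddof=2)
            if sd == 0:
                continue
            flags[order, j] = np.abs(resid) > deviation_multiplier * sd
    else:
        raise ValueError(f"unknown significance method: {method!r}")
    return flags


def marker_table(
    mz_axis: np.ndarray,
    weights: np.ndarray,
    flags: np.ndarray,
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-m/z marker table: weight and significance flag per root."""
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    if W.shape[0] != np.asarray(mz_axis).size:
        raise ValueError("weights rows must match mz axis length")
    data: dict = {"mz": np.asarray(mz_axis, dtype=float)}
    for j in range(W.shape[1]):
        data[f"weight_root{j + 1}"] = W[:, j]
    for j in range(W.shape[1]):
        data[f"flag_root{j + 1}"] = np.asarray(flags)[:, j]
    df = pd.DataFrame(data)
    if thresholds is not None:
        for j, t in enumerate(thresholds[: W.shape[1]]):
            df[f"threshold_root{j + 1}"] = t
    return df


def interpret_roots(root_scores: np.ndarray, labels: Sequence) -> pd.DataFrame:
    """Class mean scores per root, a Fig.-style reporting convenience.

    Returns a DataFrame indexed by class with one column per root; with a
    single class the summary is empty and a warning is emitted.
    """
    S = np.atleast_2d(np.asarray(root_scores, dtype=float))
    if S.shape[0] == 1 and np.asarray(root_scores).ndim == 1:
        S = S.T
    labels = np.asarray(labels)
    classes = np.unique(labels)
    cols = [f"root{j + 1}" for j in range(S.shape[1])]
    if classes.size < 2:
        warnings.warn("only one class present; root interpretation is empty")
        return pd.DataFrame(columns=cols)
    means = np.vstack([S[labels == c].mean(axis=0) for c in classes])
    return pd.DataFrame(means, index=pd.Index(classes, name="class"), columns=cols)


def isolating_root(
    root_scores: np.ndarray, labels: Sequence, target_class: str
) -> int:
    """Index (0-based) of the root that best isolates ``target_class``.

    Per root, the gap between the target class's mean score and the nearest
    other class mean is normalized by the root's pooled within-class spread;
    the root with the largest normalized gap wins.
    """
    S = np.atleast_2d(np.asarray(root_scores, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if target_class not in classes:
        raise ValueError(f"unknown class {target_class!r}")
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    best, best_gap = 0, -np.inf
    for j in range(S.shape[1]):
        col = S[:, j]
        means = {c: col[labels == c].mean() for c in classes}
        spread = np.std(
            np.concatenate([col[labels == c] - means[c] for c in classes])
        )
        spread = spread if spread > 0 else 1.0
        others = [means[c] for c in classes if c != target_class]
        gap = min(abs(means[target_class] - o) for o in others) / spread
        if gap > best_gap:
            best, best_gap = j, gap
    return best
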