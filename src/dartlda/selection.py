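"""Validation protocol: stratified splitting, bootstrap CV, forward-stepwise
PC selection and the repeated outer loop.

The protocol per repeat is:

1. split the samples into training and test sets, putting a stratified 20%
   of each class into the test set (rounding half-up);
2. fit row scaling, column scaling and PCA on the training set only, and
   reproject the test samples with the frozen column min/max and loadings;
3. forward-stepwise selection over the first K candidate PCs: at each step
   every unused PC is scored, joined to the current set, by cross-validated
   NER% (bootstrap: repeated stratified 20% exclusion from the training set,
   a fresh LDA fit per iteration), and the best one is added while the CV
   NER% strictly improves;
4. evaluate the final model on the reprojected test set.

Repeating steps 1-4 with different random test sets yields one
:class:`ValidationRecord` per repeat; the overall best model is the record
closest (in Euclidean distance) to the ideal point of 100% NER on training,
cross-validation and test simultaneously.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .lda import (
    LDAModel,
    _discriminant_matrix,
    _fit_arrays,
    classify,
    fit_lda,
    ner_percent,
)
from .pca import PCAModel, fit_pca, project
from .preprocess import (
    AlignedMatrix,
    ColumnScaling,
    apply_column_scaling,
    range_scale_columns,
    range_scale_rows,
)

__all__ = [
    "CVSettings",
    "ValidationSettings",
    "ValidationRecord",
    "ValidationArtifacts",
    "BestModel",
    "ForwardSelectionResult",
    "stratified_split",
    "bootstrap_cv_ner",
    "forward_select",
    "run_single_validation",
    "repeated_validation",
    "pick_best_model",
]

_SEED_MOD = 2**31


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n child seeds (< 2^31) deterministically from one integer."""
    return np.random.SeedSequence(seed).generate_state(n) % _SEED_MOD


def stratified_split(
    labels: Sequence, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random stratified split: per class, round(fraction·n_g) samples (half-up)
    go to the test side.

    Returns (train_indices, test_indices), each sorted ascending, disjoint and
    exhaustive.  Raises if any class would retain fewer than 2 training
    samples.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    test: list[np.ndarray] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        k = _round_half_up(fraction * idx.size)
        if idx.size - k < 2:
            raise ValueError(
                f"class {c!r}: {idx.size - k} training samples would remain (< 2)"
            )
        test.append(rng.permutation(idx)[:k])
    test_idx = np.sort(np.concatenate(test)) if test else np.empty(0, dtype=int)
    train_idx = np.setdiff1d(np.arange(labels.size), test_idx)
    return train_idx, np.asarray(test_idx, dtype=int)


@dataclass(frozen=True)
class CVSettings:
    """Bootstrap cross-validation settings."""

    n_iterations: int = 1000
    holdout_fraction: float = 0.2
    with_replacement: bool = False


def bootstrap_cv_ner(
    scores: np.ndarray,
    labels: Sequence,
    feature_indices: Sequence[int],
    n_iterations: int = 1000,
    holdout_fraction: float = 0.2,
    seed: int = 0,
    with_replacement: bool = False,
) -> float:
    """Mean NER% over bootstrap iterations of stratified 20% exclusion.

    Each iteration excludes a stratified ``holdout_fraction`` of the samples
    (without replacement; the half-up rounding matches the outer split), fits
    the pooled-covariance LDA on the remainder and scores the excluded
    samples; the per-iteration NER% values are averaged.

    With ``with_replacement=True`` each iteration instead resamples every
    class with replacement to its own size for training and scores the
    out-of-bag samples (classic bootstrap), skipping iterations whose bag
    leaves a class with fewer than 2 distinct training samples.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    X = np.asarray(scores, dtype=float)[:, np.asarray(list(feature_indices), dtype=int)]
    labels = np.asarray(labels)
    classes, codes = np.unique(labels, return_inverse=True)
    G = classes.size
    class_idx = [np.flatnonzero(codes == g) for g in range(G)]
    ks = [_round_half_up(holdout_fraction * idx.size) for idx in class_idx]
    for idx, k in zip(class_idx, ks):
        if idx.size - k < 2:
            raise ValueError("holdout leaves fewer than 2 training samples in a class")
    if sum(ks) == 0:
        raise ValueError("holdout fraction excludes no samples")

    rng = np.random.default_rng(seed)
    log_priors = np.full(G, -np.log(G))
    total = 0.0
    done = 0
    for _ in range(n_iterations):
        if with_replacement:
            train_parts, hold_parts = [], []
            for idx in class_idx:
                bag = rng.integers(0, idx.size, size=idx.size)
                train_parts.append(idx[bag])
                oob = idx[np.setdiff1d(np.arange(idx.size), bag, assume_unique=False)]
                hold_parts.append(oob)
            train = np.concatenate(train_parts)
            hold = np.concatenate(hold_parts)
            if hold.size == 0 or any(
                np.unique(t).size < 2 for t in train_parts
            ):
                continue
        else:
            hold_parts = [rng.permutation(idx)[:k] for idx, k in zip(class_idx, ks)]
            hold = np.concatenate(hold_parts)
            train = np.setdiff1d(np.arange(labels.size), hold)
        try:
            cent, _, chol, log_det = _fit_arrays(X[train], codes[train], G)
        except ValueError:
            continue
        D = _discriminant_matrix(X[hold], cent, chol, log_det, log_priors)
        pred = np.argmin(D, axis=1)
        total += 100.0 * np.mean(pred == codes[hold])
        done += 1
    if done == 0:
        raise ValueError("no valid bootstrap iteration could be completed")
    return total / done


@dataclass
class ForwardSelectionResult:
    """Ordered selected PC indices (0-based) and the CV-NER% path."""

    selected: list[int]
    cv_path: list[float]


def forward_select(
    scores: np.ndarray,
    labels: Sequence,
    candidate_pcs: Sequence[int] | None = None,
    cv: CVSettings | None = None,
    seed: int = 0,
) -> ForwardSelectionResult:
    """Greedy forward-stepwise PC selection by cross-validated NER%.

    At each step every unused candidate is appended in turn to the current
    set and scored by :func:`bootstrap_cv_ner`; all candidates within one step
    share the same CV split seed, so comparisons are paired.  The candidate
    with the highest CV NER% is added (ties to the lower PC index); selection
    stops when no candidate strictly improves the CV NER%.
    """
    X = np.asarray(scores, dtype=float)
    if candidate_pcs is None:
        candidate_pcs = range(min(20, X.shape[1]))
    remaining = list(dict.fromkeys(int(c) for c in candidate_pcs))
    if not remaining:
        raise ValueError("candidate PC pool is empty")
    cv = cv or CVSettings()
    step_seeds = _spawn_seeds(seed, len(remaining))

    selected: list[int] = []
    cv_path: list[float] = []
    best_so_far = -np.inf
    for step, step_seed in enumerate(step_seeds):
        best_ner, best_c = -np.inf, None
        for c in remaining:
            ner = bootstrap_cv_ner(
                X,
                labels,
                selected + [c],
                n_iterations=cv.n_iterations,
                holdout_fraction=cv.holdout_fraction,
                seed=int(step_seed),
                with_replacement=cv.with_replacement,
            )
            if ner > best_ner:  # ties keep the earlier (lower-index) candidate
                best_ner, best_c = ner, c
        if best_c is None or best_ner <= best_so_far:
            break
        selected.append(best_c)
        cv_path.append(best_ner)
        remaining.remove(best_c)
        best_so_far = best_ner
        if not remaining:
            break
    return ForwardSelectionResult(selected, cv_path)


@dataclass(frozen=True)
class ValidationSettings:
    """Settings for one full split-train-test cycle."""

    test_fraction: float = 0.2
    n_candidate_pcs: int = 20
    cv: CVSettings = field(default_factory=CVSettings)
    row_range: tuple[float, float] = (0.0, 1.0)
    col_range: tuple[float, float] = (0.0, 1.0)


@dataclass
class ValidationRecord:
    """One repeat's outcome: the selected PCs and the NER% triple."""

    repeat_index: int
    split_seed: int
    selected_pcs: tuple[int, ...]  # 0-based PC indices, selection order
    ner_train: float
    ner_cv: float
    ner_test: float


@dataclass
class ValidationArtifacts:
    """Fitted objects of one repeat, for marker analysis and leakage checks."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    col_scaling: ColumnScaling
    pca: PCAModel
    test_scores: np.ndarray
    lda: LDAModel
    cv_path: list[float]


@dataclass
class BestModel:
    """The record closest to the ideal (100, 100, 100) NER point."""

    record: ValidationRecord
    distance_to_ideal: float


def run_single_validation(
    matrix: AlignedMatrix,
    split_seed: int,
    settings: ValidationSettings | None = None,
    repeat_index: int = 0,
) -> tuple[ValidationRecord, ValidationArtifacts]:
    """One split-scale-PCA-select-test cycle with training-only fitting.

    Row scaling is per-sample (self-contained, hence identical for training
    and test rows); column scaling and PCA are fitted on training rows only
    and applied frozen to the test rows.
    """
    settings = settings or ValidationSettings()
    labels = np.asarray(matrix.labels)
    train_idx, test_idx = stratified_split(labels, settings.test_fraction, split_seed)

    rows = range_scale_rows(matrix, *settings.row_range)
    train = rows.subset(train_idx)
    test = rows.subset(test_idx)
    train_cs = range_scale_columns(train, *settings.col_range)
    col_params = train_cs.col_scaling
    test_cs = apply_column_scaling(test, col_params)

    k = min(settings.n_candidate_pcs, train_idx.size - 1, matrix.n_variables)
    pca = fit_pca(train_cs, k)
    test_scores = project(pca, test_cs)

    fs_seed = int(_spawn_seeds(split_seed, 1)[0])
    fs = forward_select(
        pca.training_scores, labels[train_idx], range(k), settings.cv, fs_seed
    )
    lda = fit_lda(pca.training_scores, labels[train_idx], fs.selected)
    ner_train = ner_percent(labels[train_idx], classify(lda, pca.training_scores))
    ner_cv = fs.cv_path[-1] if fs.cv_path else float("nan")
    if test_idx.size:
        ner_test = ner_percent(labels[test_idx], classify(lda, test_scores))
    else:
        ner_test = float("nan")

    record = ValidationRecord(
        repeat_index, int(split_seed), tuple(fs.selected), ner_train, ner_cv, ner_test
    )
    artifacts = ValidationArtifacts(
        train_idx, test_idx, col_params, pca, test_scores, lda, fs.cv_path
    )
    return record, artifacts


def repeated_validation(
    matrix: AlignedMatrix,
    n_repeats: int = 100,
    seed: int = 0,
    settings: ValidationSettings | None = None,
) -> list[ValidationRecord]:
    """Repeat the full validation cycle with a fresh random test set each time."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    split_seeds = _spawn_seeds(seed, n_repeats)
    records = []
    for r, s in enumerate(split_seeds):
        rec, _ = run_single_validation(matrix, int(s), settings, repeat_index=r)
        records.append(rec)
    return records


def pick_best_model(records: Sequence[ValidationRecord]) -> BestModel:
    """Record with minimal Euclidean distance from (100, 100, 100) in
    (NER_train, NER_cv, NER_test) space; ties go to the earlier repeat."""
    if not records:
        raise ValueError("no validation records supplied")
    best, best_d = None, np.inf
    for rec in records:
        triple = np.array([rec.ner_train, rec.ner_cv, rec.ner_test])
        if np.any(np.isnan(triple)):
            continue
        d = float(np.linalg.norm(100.0 - triple))
        if d < best_d:
            best, best_d = rec, d
    if best is None:
        raise ValueError("all records carry undefined NER values")
    return BestModel(best, best_d)
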