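"""End-to-end orchestration: simulate or ingest, preprocess, validate,
extract markers, and write all stage artifacts to disk.

One global seed expands deterministically into per-stage seeds (via
``numpy.random.SeedSequence``), so a single integer reproduces an entire run
bit-exactly.  Default iteration counts are scaled down (25 repeats, 100
bootstrap iterations); :meth:`RunConfig.full_scale` restores the full
protocol (100 repeats, 1000 iterations).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .canonical import (
    canonical_analysis,
    interpret_roots,
    isolating_root,
    marker_table,
    significant_weights,
    variable_weights,
)
from .pca import explained_variance_report, fit_pca
from .preprocess import AlignedMatrix, align_spectra, range_scale_columns, range_scale_rows
from .selection import (
    CVSettings,
    ValidationSettings,
    pick_best_model,
    repeated_validation,
    run_single_validation,
)
from .simulate import (
    SyntheticConfig,
    generate_dataset,
    generate_temperature_dataset,
    parchment_only_config,
)

__all__ = ["RunConfig", "run_full_analysis", "run_temperature_study", "stage_seeds"]

logger = logging.getLogger("dartlda")

_SEED_MOD = 2**31


def stage_seeds(seed: int, names: Sequence[str]) -> dict[str, int]:
    """Expand one global seed into named per-stage seeds (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(len(names)) % _SEED_MOD
    return {name: int(s) for name, s in zip(names, state)}


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    manifest: str | None = None  # required in files mode
    out_dir: str = "results/run"
    seed: int = 0
    tolerance: float = 0.01
    row_range: tuple[float, float] = (0.0, 1.0)
    col_range: tuple[float, float] = (0.0, 1.0)
    n_candidate_pcs: int = 20
    n_repeats: int = 25
    cv_iterations: int = 100
    test_fraction: float = 0.2
    holdout_fraction: float = 0.2
    marker_method: str = "fixed"
    marker_thresholds: tuple[float, float] = (0.1, 0.05)

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not self.manifest:
            raise ValueError("files mode requires a manifest path")
        for name in ("n_candidate_pcs", "n_repeats", "cv_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        for lo, hi in (self.row_range, self.col_range):
            if not hi > lo:
                raise ValueError("scaling ranges must have hi > lo")
        if not 0 < self.test_fraction < 1 or not 0 < self.holdout_fraction < 1:
            raise ValueError("fractions must be in (0, 1)")

    @classmethod
    def full_scale(cls, **kwargs) -> "RunConfig":
        """Full protocol: 100 repeats × 1000 bootstrap iterations."""
        kwargs.setdefault("n_repeats", 100)
        kwargs.setdefault("cv_iterations", 1000)
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh)
        for key in ("row_range", "col_range", "marker_thresholds"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _load_spectra(config: RunConfig, seed: int):
    if config.mode == "files":
        return dio.read_dataset(config.manifest)
    return generate_dataset(parchment_only_config(), seed)


def _validation_settings(config: RunConfig) -> ValidationSettings:
    return ValidationSettings(
        test_fraction=config.test_fraction,
        n_candidate_pcs=config.n_candidate_pcs,
        cv=CVSettings(
            n_iterations=config.cv_iterations,
            holdout_fraction=config.holdout_fraction,
        ),
        row_range=config.row_range,
        col_range=config.col_range,
    )


def records_table(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "repeat": [r.repeat_index for r in records],
            "split_seed": [r.split_seed for r in records],
            "n_pcs": [len(r.selected_pcs) for r in records],
            "selected_pcs": [
                "+".join(f"PC{i + 1}" for i in r.selected_pcs) for r in records
            ],
            "ner_train": [r.ner_train for r in records],
            "ner_cv": [r.ner_cv for r in records],
            "ner_test": [r.ner_test for r in records],
        }
    )


def summary_table(records) -> pd.DataFrame:
    """Min/max of model size and of the three NER% values across repeats."""
    df = records_table(records)
    rows = []
    for col, label in [
        ("n_pcs", "Number of PCs included"),
        ("ner_train", "NER% training set"),
        ("ner_cv", "NER% cross-validation"),
        ("ner_test", "NER% test set"),
    ]:
        rows.append({"quantity": label, "min": df[col].min(), "max": df[col].max()})
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole pipeline and write every stage artifact under out_dir.

    Returns a summary dict (also written as ``summary.json``) with the
    best-model NER triple, its selected PCs, per-class metrics and the
    significant markers per canonical root.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    seeds = stage_seeds(config.seed, ["simulate", "validation"])
    t0 = time.perf_counter()

    spectra = _load_spectra(config, seeds["simulate"])
    matrix = align_spectra(spectra, config.tolerance)
    dio.write_matrix(matrix, out / "matrix")
    logger.info(
        "aligned %d spectra onto %d m/z positions (%.2fs)",
        matrix.n_samples, matrix.n_variables, time.perf_counter() - t0,
    )

    settings = _validation_settings(config)
    records = repeated_validation(
        matrix, config.n_repeats, seeds["validation"], settings
    )
    records_table(records).to_csv(out / "records.tsv", sep="\t", index=False)
    summary_table(records).to_csv(out / "summary_table.tsv", sep="\t", index=False)

    best = pick_best_model(records)
    # rebuild the best repeat's fitted objects from its split seed
    _, art = run_single_validation(
        matrix, best.record.split_seed, settings, best.record.repeat_index
    )
    selected = list(best.record.selected_pcs)
    labels = np.asarray(matrix.labels)
    train_labels = labels[art.train_indices]

    canon = canonical_analysis(art.pca.training_scores[:, selected], train_labels)
    weights = variable_weights(art.pca.loadings[:, selected], canon.root_coefficients)
    flags = significant_weights(
        weights, config.marker_method, config.marker_thresholds
    )
    markers = marker_table(matrix.mz_axis, weights, flags, config.marker_thresholds)
    markers.to_csv(out / "markers.tsv", sep="\t", index=False)
    roots = interpret_roots(canon.root_scores, train_labels)
    roots.to_csv(out / "root_class_means.tsv", sep="\t")

    sig_mz = {
        f"root{j + 1}": [float(v) for v in markers.loc[flags[:, j], "mz"]]
        for j in range(flags.shape[1])
    }
    summary = {
        "n_samples": matrix.n_samples,
        "n_variables": matrix.n_variables,
        "n_repeats": config.n_repeats,
        "cv_iterations": config.cv_iterations,
        "best_model": {
            "repeat": best.record.repeat_index,
            "selected_pcs": [f"PC{i + 1}" for i in selected],
            "ner_train": best.record.ner_train,
            "ner_cv": best.record.ner_cv,
            "ner_test": best.record.ner_test,
            "distance_to_ideal": best.distance_to_ideal,
        },
        "ner_test_min": float(min(r.ner_test for r in records)),
        "ner_test_max": float(max(r.ner_test for r in records)),
        "significant_markers": sig_mz,
        "runtime_s": round(time.perf_counter() - t0, 2),
    }
    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2)
    logger.info("full analysis done in %.1fs", summary["runtime_s"])
    return summary


def run_temperature_study(
    config: RunConfig,
    synthetic_config: SyntheticConfig | None = None,
) -> dict:
    """Single PCA over all temperature levels with class × temperature scores.

    The matrix is columnwise range scaled onto ``config.col_range`` (the
    temperature design uses (−1, 1)); score and explained-variance tables plus
    per-class centroid-displacement summaries are written under out_dir.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed, ["simulate_temperature"])

    if config.mode == "files":
        spectra = dio.read_dataset(config.manifest)
        if any(s.temperature is None for s in spectra):
            raise ValueError("temperature study requires temperature metadata")
    else:
        syn = synthetic_config or parchment_only_config()
        spectra = generate_temperature_dataset(syn, seeds["simulate_temperature"])

    matrix = align_spectra(spectra, config.tolerance)
    if matrix.temperatures is None:
        raise ValueError("aligned matrix carries no temperature metadata")
    scaled = range_scale_columns(matrix, *config.col_range)
    k = min(config.n_candidate_pcs, matrix.n_samples - 1, matrix.n_variables)
    pca = fit_pca(scaled, k)

    scores = pd.DataFrame(
        pca.training_scores, columns=[f"PC{i + 1}" for i in range(k)]
    )
    scores.insert(0, "sample_id", matrix.sample_ids)
    scores.insert(1, "class", matrix.labels)
    scores.insert(2, "temperature", matrix.temperatures)
    scores.to_csv(out / "temperature_scores.tsv", sep="\t", index=False)

    ev = pd.DataFrame(
        explained_variance_report(pca), columns=["pc", "explained_variance_pct"]
    )
    ev.to_csv(out / "temperature_variance.tsv", sep="\t", index=False)

    # per-class centroid displacement across temperatures, in PC space
    disp_rows = []
    for cls in sorted(set(matrix.labels)):
        mask = np.asarray(matrix.labels) == cls
        temps = sorted(set(matrix.temperatures[mask]))
        cents = {
            t: pca.training_scores[mask & (matrix.temperatures == t)].mean(axis=0)
            for t in temps
        }
        disp = max(
            float(np.linalg.norm(cents[a] - cents[b]))
            for a in temps
            for b in temps
        )
        disp_rows.append({"class": cls, "max_centroid_displacement": disp})
    disp_df = pd.DataFrame(disp_rows)
    disp_df.to_csv(out / "temperature_displacement.tsv", sep="\t", index=False)

    result = {
        "n_samples": matrix.n_samples,
        "n_variables": matrix.n_variables,
        "explained_variance_pct": [float(v) for _, v in explained_variance_report(pca)][:5],
        "centroid_displacement": {
            row["class"]: row["max_centroid_displacement"] for _, row in disp_df.iterrows()
        },
    }
    with (out / "temperature_summary.json").open("w") as fh:
        json.dump(result, fh, indent=2)
    return result
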