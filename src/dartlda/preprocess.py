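"""Peak alignment, range scaling and TIC computation.

Heterogeneous centroided peak lists are matched onto one common m/z grid by
greedy single-linkage clustering: all peaks from all samples are swept in
ascending m/z order and a peak joins the current cluster when its m/z lies
within ``tolerance`` of the cluster's running intensity-weighted centroid.
Each cluster becomes one column of the sample × m/z intensity matrix; a
sample with no peak in a cluster contributes intensity 0 there.

Range scaling maps each row (sample) or column (m/z variable) affinely onto
a target interval using its own min and max.  Rowwise scaling removes
sample-amount effects (each spectrum is self-normalized); columnwise scaling
puts all m/z variables on a common footing before PCA.  Column min/max are
recorded at fit time so the identical transform can be applied to held-out
samples (whose scaled values may then fall outside the target interval).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra import PeakSpectrum

__all__ = [
    "AlignedMatrix",
    "RowScaling",
    "ColumnScaling",
    "align_spectra",
    "range_scale_rows",
    "range_scale_columns",
    "apply_column_scaling",
    "total_ion_current",
    "combine_scans",
]


@dataclass
class RowScaling:
    """Per-row affine scaling parameters (min/max recorded at fit time)."""

    lo: float
    hi: float
    row_min: np.ndarray  # (N,)
    row_max: np.ndarray  # (N,)

    def invert(self, X_scaled: np.ndarray) -> np.ndarray:
        """Map scaled values back to the raw scale (degenerate rows -> row_min)."""
        span = (self.row_max - self.row_min)[:, None]
        return self.row_min[:, None] + (X_scaled - self.lo) * span / (self.hi - self.lo)


@dataclass
class ColumnScaling:
    """Per-column affine scaling parameters, reusable on held-out samples."""

    lo: float
    hi: float
    col_min: np.ndarray  # (P,)
    col_max: np.ndarray  # (P,)

    def apply(self, X: np.ndarray) -> np.ndarray:
        span = self.col_max - self.col_min
        safe = np.where(span > 0, span, 1.0)
        scaled = self.lo + (X - self.col_min) * (self.hi - self.lo) / safe
        return np.where(span > 0, scaled, self.lo)

    def invert(self, X_scaled: np.ndarray) -> np.ndarray:
        span = self.col_max - self.col_min
        return self.col_min + (X_scaled - self.lo) * span / (self.hi - self.lo)


@dataclass
class AlignedMatrix:
    """Samples × common-m/z-grid intensity table with labels and scaling state.

    ``scaling_state`` is one of ``raw``, ``row_scaled``, ``column_scaled`` or
    ``row_then_column_scaled``; the row/column parameters recorded when a
    scaling was fitted live in ``row_scaling`` / ``col_scaling``.
    """

    mz_axis: np.ndarray  # (P,) strictly increasing
    X: np.ndarray  # (N, P)
    sample_ids: list[str]
    labels: list[str]
    temperatures: np.ndarray | None = None
    scaling_state: str = "raw"
    row_scaling: RowScaling | None = None
    col_scaling: ColumnScaling | None = None

    def __post_init__(self) -> None:
        self.mz_axis = np.asarray(self.mz_axis, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if self.mz_axis.size != p:
            raise ValueError("mz_axis length must match number of columns")
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels length must match number of rows")
        if self.mz_axis.size > 1 and np.any(np.diff(self.mz_axis) <= 0):
            raise ValueError("mz_axis must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: Sequence[int]) -> "AlignedMatrix":
        """Row subset preserving m/z axis, labels and scaling state."""
        rows = np.asarray(rows, dtype=int)
        temps = self.temperatures[rows] if self.temperatures is not None else None
        return AlignedMatrix(
            self.mz_axis.copy(),
            self.X[rows].copy(),
            [self.sample_ids[i] for i in rows],
            [self.labels[i] for i in rows],
            temps,
            self.scaling_state,
            None,  # per-row params do not survive subsetting
            self.col_scaling,
        )

    def copy(self) -> "AlignedMatrix":
        temps = self.temperatures.copy() if self.temperatures is not None else None
        return AlignedMatrix(
            self.mz_axis.copy(), self.X.copy(), list(self.sample_ids),
            list(self.labels), temps, self.scaling_state,
            self.row_scaling, self.col_scaling,
        )


def align_spectra(spectra: Sequence[PeakSpectrum], tolerance: float = 0.01) -> AlignedMatrix:
    """Match peak lists onto a common m/z grid.

    Greedy single-linkage clustering on the pooled, m/z-sorted peak list: a
    peak whose m/z is within ``tolerance`` Da of the current cluster's running
    intensity-weighted centroid joins that cluster, otherwise it opens a new
    one.  Each cluster becomes one matrix column located at its final
    intensity-weighted mean m/z; multiple peaks of one sample falling in the
    same cluster have their intensities summed.

    Parameters
    ----------
    spectra : sequence of PeakSpectrum
        Nonempty list of centroided spectra.
    tolerance : float
        Maximum centroid distance in Da for joining a cluster (default 0.01,
        matching ~6000 mass resolution over the 50-800 Da window).
    """
    if len(spectra) == 0:
        raise ValueError("cannot align an empty list of spectra")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    mz_all = np.concatenate([s.mz for s in spectra]) if spectra else np.empty(0)
    int_all = np.concatenate([s.intensity for s in spectra])
    samp_all = np.concatenate(
        [np.full(s.n_peaks, i, dtype=int) for i, s in enumerate(spectra)]
    )
    order = np.argsort(mz_all, kind="stable")

    centroids: list[float] = []
    members_sample: list[list[int]] = []
    members_intensity: list[list[float]] = []
    sum_w = sum_wm = 0.0
    sum_m = 0.0
    count = 0

    def _centroid() -> float:
        return sum_wm / sum_w if sum_w > 0 else sum_m / count

    for j in order:
        mz, inten, samp = mz_all[j], int_all[j], samp_all[j]
        if count and mz - _centroid() <= tolerance:
            sum_w += inten
            sum_wm += inten * mz
            sum_m += mz
            count += 1
            members_sample[-1].append(int(samp))
            members_intensity[-1].append(float(inten))
        else:
            if count:
                centroids.append(_centroid())
            sum_w, sum_wm, sum_m, count = inten, inten * mz, mz, 1
            members_sample.append([int(samp)])
            members_intensity.append([float(inten)])
    if count:
        centroids.append(_centroid())

    mz_axis = np.asarray(centroids)
    n, p = len(spectra), mz_axis.size
    X = np.zeros((n, p))
    for col, (samps, intens) in enumerate(zip(members_sample, members_intensity)):
        np.add.at(X[:, col], samps, intens)

    temps = np.asarray(
        [np.nan if s.temperature is None else s.temperature for s in spectra]
    )
    temperatures = None if np.all(np.isnan(temps)) else temps
    return AlignedMatrix(
        mz_axis,
        X,
        [s.sample_id for s in spectra],
        [s.class_label for s in spectra],
        temperatures,
    )


def _check_range(lo: float, hi: float) -> None:
    if not hi > lo:
        raise ValueError(f"invalid scaling range: hi ({hi}) must exceed lo ({lo})")


def range_scale_rows(m: AlignedMatrix, lo: float = 0.0, hi: float = 1.0) -> AlignedMatrix:
    """Affinely map each row onto [lo, hi] using its own min/max.

    Constant (degenerate) rows map to ``lo``.  Scaling is self-contained per
    sample, so the same rule applies identically to training and held-out
    spectra.
    """
    _check_range(lo, hi)
    X = m.X
    rmin = X.min(axis=1)
    rmax = X.max(axis=1)
    span = rmax - rmin
    safe = np.where(span > 0, span, 1.0)
    scaled = lo + (X - rmin[:, None]) * (hi - lo) / safe[:, None]
    scaled = np.where(span[:, None] > 0, scaled, lo)
    state = "row_scaled" if m.scaling_state == "raw" else m.scaling_state
    out = m.copy()
    out.X = scaled
    out.scaling_state = state
    out.row_scaling = RowScaling(lo, hi, rmin, rmax)
    return out


def range_scale_columns(m: AlignedMatrix, lo: float = 0.0, hi: float = 1.0) -> AlignedMatrix:
    """Affinely map each column onto [lo, hi]; records per-column min/max.

    Constant columns map to ``lo``.  The recorded :class:`ColumnScaling` can be
    applied to held-out samples with :func:`apply_column_scaling`; held-out
    values may then legitimately fall outside [lo, hi].
    """
    _check_range(lo, hi)
    params = ColumnScaling(lo, hi, m.X.min(axis=0), m.X.max(axis=0))
    out = m.copy()
    out.X = params.apply(m.X)
    out.scaling_state = (
        "row_then_column_scaled" if m.scaling_state == "row_scaled" else "column_scaled"
    )
    out.col_scaling = params
    return out


def apply_column_scaling(m: AlignedMatrix, params: ColumnScaling) -> AlignedMatrix:
    """Apply previously fitted column scaling (e.g. to reprojected test samples)."""
    if params.col_min.size != m.n_variables:
        raise ValueError("column scaling parameters do not match matrix width")
    out = m.copy()
    out.X = params.apply(m.X)
    out.scaling_state = (
        "row_then_column_scaled" if m.scaling_state == "row_scaled" else "column_scaled"
    )
    out.col_scaling = params
    return out


def total_ion_current(series: Sequence[PeakSpectrum]) -> np.ndarray:
    """Per-scan summed intensity over a time-ordered scan series.

    Returns an (n_scans, 2) array of (scan time, summed intensity); scan time
    is the acquisition index in seconds (one spectrum per second).
    """
    n = len(series)
    out = np.empty((n, 2))
    out[:, 0] = np.arange(n, dtype=float)
    out[:, 1] = [s.tic for s in series]
    return out


def combine_scans(
    scans: Sequence[PeakSpectrum],
    sample_id: str | None = None,
    tolerance: float = 0.01,
) -> PeakSpectrum:
    """Average a sample's scan window into one representative spectrum.

    Scans are aligned onto a common grid and the mean intensity per grid
    position is taken, so each sample contributes a single peak list to the
    downstream matrix.
    """
    if len(scans) == 0:
        raise ValueError("cannot combine zero scans")
    m = align_spectra(scans, tolerance)
    mean_int = m.X.mean(axis=0)
    first = scans[0]
    return PeakSpectrum(
        sample_id or first.sample_id,
        first.class_label,
        m.mz_axis,
        mean_int,
        first.temperature,
    )
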