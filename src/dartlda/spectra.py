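"""Containers for centroided mass spectra.

A :class:`PeakSpectrum` holds one sample's centroided peak list — strictly
increasing m/z values with nonnegative intensities — together with its class
label and, when the acquisition varied the ion-source gas temperature, the
temperature in °C.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["PeakSpectrum"]


@dataclass
class PeakSpectrum:
    """One sample's centroided peak list plus metadata.

    Parameters
    ----------
    sample_id : str
        Unique sample identifier.
    class_label : str
        Treatment class (e.g. ``"untreated_parchment"``).
    mz : array of float
        Strictly increasing m/z values in Da, all positive.
    intensity : array of float
        Nonnegative intensities (counts), same length as ``mz``.
    temperature : float, optional
        Ion-source gas temperature in °C, if recorded.
    """

    sample_id: str
    class_label: str
    mz: np.ndarray
    intensity: np.ndarray
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be one-dimensional")
        if self.mz.shape != self.intensity.shape:
            raise ValueError(
                f"mz and intensity lengths differ ({self.mz.size} vs {self.intensity.size})"
            )
        if self.mz.size:
            if np.any(self.mz <= 0):
                raise ValueError("all m/z values must be positive")
            if np.any(np.diff(self.mz) <= 0):
                raise ValueError("m/z values must be strictly increasing (sorted, unique)")
            if np.any(self.intensity < 0):
                raise ValueError("intensities must be nonnegative")

    @classmethod
    def from_pairs(
        cls,
        sample_id: str,
        class_label: str,
        pairs: Iterable[tuple[float, float]],
        temperature: float | None = None,
    ) -> "PeakSpectrum":
        """Build a spectrum from (mz, intensity) pairs, sorting by m/z."""
        pairs = list(pairs)
        if pairs:
            mz, inten = (np.asarray(a, dtype=float) for a in zip(*pairs))
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
        else:
            mz = np.empty(0)
            inten = np.empty(0)
        return cls(sample_id, class_label, mz, inten, temperature)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def tic(self) -> float:
        """Summed intensity of all peaks (one scan's total ion current)."""
        return float(self.intensity.sum())

    def copy(self) -> "PeakSpectrum":
        return PeakSpectrum(
            self.sample_id,
            self.class_label,
            self.mz.copy(),
            self.intensity.copy(),
            self.temperature,
        )
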