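"""Synthetic DART-MS peak-list generator.

The instrument data behind this kind of study are rarely deposited, so the
generator produces labeled centroided peak lists carrying the statistical
structure the analysis pipeline assumes:

* five treatment classes with the study sizes (19 untreated parchment,
  28 castor-oil-treated parchment, 21 glycerol-treated parchment, 16 castor
  oil standards, 22 glycerol standards — 106 samples in total; the
  parchment-only subset has 68);
* glycerol classes marked by peaks at m/z 93.049 (protonated glycerol),
  110.058 (water adduct) and 185.063 (protonated dimer);
* untreated and castor-oil-treated parchment sharing one lipid-like peak
  backbone, so their raw spectra strongly overlap and differ only in a few
  moderate castor-specific signals;
* high within-class dispersion for the parchment/castor-oil classes and low
  dispersion for the glycerol classes;
* a three-level ion-source temperature design (23/45/90 °C, 69/78/85 samples
  per level, 232 total over the three parchment classes) in which higher
  temperature both separates the class centroids further and widens the
  within-class spread — except for the glycerol class, which stays put.

Per-peak intensities are truncated-at-zero normal draws around the class
mean with a class dispersion multiplier on the peak spread plus additive
baseline noise; peak m/z positions are jittered by a small normal
perturbation (well inside the alignment tolerance).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .spectra import PeakSpectrum

__all__ = [
    "ClassSpec",
    "TemperatureLevel",
    "SyntheticConfig",
    "GLYCEROL_MARKERS",
    "CASTOR_MARKERS",
    "default_study_config",
    "parchment_only_config",
    "generate_dataset",
    "generate_temperature_dataset",
]

#: Glycerol marker peaks: (m/z in Da, mean intensity, intensity sd) on parchment.
GLYCEROL_MARKERS: tuple[tuple[float, float, float], ...] = (
    (93.049, 5000.0, 600.0),   # M+H+
    (110.058, 2500.0, 400.0),  # M+H2O adduct
    (185.063, 3500.0, 500.0),  # M+M+H+ dimer
)

#: Castor-oil ricinoleate-like marker peaks on treated parchment.
CASTOR_MARKERS: tuple[tuple[float, float, float], ...] = (
    (281.248, 1200.0, 300.0),
    (299.259, 900.0, 250.0),
    (316.285, 700.0, 200.0),
)

_PARCHMENT_CLASSES = (
    "untreated_parchment",
    "castor_parchment",
    "glycerol_parchment",
)


@dataclass(frozen=True)
class ClassSpec:
    """One treatment class: sample count, markers, shared backbone, spread."""

    name: str
    n_samples: int
    marker_peaks: tuple[tuple[float, float, float], ...] = ()
    backbone_id: str | None = None
    dispersion: float = 1.0  # multiplies each peak's intensity sd
    mz_jitter_sd: float = 0.002  # Da

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"class {self.name!r}: n_samples must be >= 1")
        if self.dispersion < 0:
            raise ValueError(f"class {self.name!r}: dispersion must be >= 0")
        mzs = [p[0] for p in self.marker_peaks]
        if any(m <= 0 for m in mzs):
            raise ValueError(f"class {self.name!r}: marker m/z must be positive")
        if len(set(mzs)) != len(mzs):
            raise ValueError(f"class {self.name!r}: duplicate marker m/z")
        if any(p[1] < 0 for p in self.marker_peaks):
            raise ValueError(f"class {self.name!r}: marker mean intensity < 0")


@dataclass(frozen=True)
class TemperatureLevel:
    """One ion-source temperature condition.

    ``separation`` multiplies class-specific marker means, ``backbone_gain``
    the shared-backbone means and ``spread`` the dispersion — all only for
    the temperature-responsive (non-glycerol) parchment classes.
    ``class_counts`` gives the per-class sample counts in the order of the
    parchment classes of the config.
    """

    celsius: float
    separation: float = 1.0
    spread: float = 1.0
    backbone_gain: float = 1.0
    class_counts: tuple[int, ...] = ()


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration (classes, backbones, noise, temperatures)."""

    classes: tuple[ClassSpec, ...]
    shared_backbones: Mapping[str, tuple[tuple[float, float, float], ...]]
    mz_range: tuple[float, float] = (50.0, 800.0)
    baseline_noise_sd: float = 30.0
    temperature_levels: tuple[TemperatureLevel, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        if not self.mz_range[1] > self.mz_range[0] > 0:
            raise ValueError("invalid m/z range")
        for c in self.classes:
            c.validate()
            if c.backbone_id is not None and c.backbone_id not in self.shared_backbones:
                raise ValueError(f"unknown backbone {c.backbone_id!r}")
            for mz, _, _ in self._class_peaks(c):
                if not self.mz_range[0] <= mz <= self.mz_range[1]:
                    raise ValueError(f"peak m/z {mz} outside instrument window")

    def _class_peaks(self, spec: ClassSpec) -> list[tuple[float, float, float]]:
        peaks = list(self.shared_backbones.get(spec.backbone_id, ())) if spec.backbone_id else []
        peaks.extend(spec.marker_peaks)
        peaks.sort(key=lambda p: p[0])
        return peaks

    @property
    def n_samples(self) -> int:
        return sum(c.n_samples for c in self.classes)


def _deterministic_backbone(
    rng_seed: int,
    n_peaks: int,
    mz_lo: float,
    mz_hi: float,
    intensity_range: tuple[float, float],
    avoid: Sequence[float],
    min_gap: float = 2.0,
) -> tuple[tuple[float, float, float], ...]:
    """Fixed pseudo-random peak set; pure function of its arguments."""
    rng = np.random.default_rng(rng_seed)
    mzs: list[float] = []
    while len(mzs) < n_peaks:
        cand = float(rng.uniform(mz_lo, mz_hi))
        if all(abs(cand - m) >= min_gap for m in mzs + list(avoid)):
            mzs.append(cand)
    mzs.sort()
    means = rng.uniform(*intensity_range, size=n_peaks)
    return tuple((m, float(v), float(0.25 * v)) for m, v in zip(mzs, means))


_AVOID = [m for m, _, _ in GLYCEROL_MARKERS] + [m for m, _, _ in CASTOR_MARKERS]

_DEFAULT_TEMPERATURE_LEVELS = (
    TemperatureLevel(23.0, separation=1.0, spread=1.0, backbone_gain=1.0,
                     class_counts=(19, 29, 21)),
    TemperatureLevel(45.0, separation=1.6, spread=1.4, backbone_gain=1.35,
                     class_counts=(22, 32, 24)),
    TemperatureLevel(90.0, separation=2.6, spread=2.0, backbone_gain=1.8,
                     class_counts=(24, 35, 26)),
)


def default_study_config() -> SyntheticConfig:
    """Five-class treatment study with sizes 19/28/21/16/22 (106 samples).

    Pure function: repeated calls return identical configurations.
    """
    backbones = {
        "parchment": _deterministic_backbone(
            20160911, 45, 60.0, 780.0, (200.0, 3000.0), _AVOID
        ),
        "castor_oil": _deterministic_backbone(
            20160912, 12, 150.0, 620.0, (500.0, 4000.0), _AVOID
        )
        + tuple((mz, 5.0 * mean, 5.0 * sd) for mz, mean, sd in CASTOR_MARKERS),
        "glycerol": _deterministic_backbone(
            20160913, 5, 60.0, 400.0, (100.0, 600.0), _AVOID
        ),
    }
    classes = (
        ClassSpec("untreated_parchment", 19, (), "parchment", dispersion=1.6),
        ClassSpec("castor_parchment", 28, CASTOR_MARKERS, "parchment", dispersion=1.6),
        ClassSpec("glycerol_parchment", 21, GLYCEROL_MARKERS, "parchment", dispersion=0.7),
        ClassSpec("castor_standard", 16, (), "castor_oil", dispersion=1.0),
        ClassSpec(
            "glycerol_standard",
            22,
            tuple((mz, 1.8 * mean, 1.3 * sd) for mz, mean, sd in GLYCEROL_MARKERS),
            "glycerol",
            dispersion=0.7,
        ),
    )
    cfg = SyntheticConfig(
        classes=classes,
        shared_backbones=backbones,
        temperature_levels=_DEFAULT_TEMPERATURE_LEVELS,
    )
    cfg.validate()
    return cfg


def parchment_only_config() -> SyntheticConfig:
    """Three-class parchment subset (19/28/21, 68 samples) of the study config."""
    full = default_study_config()
    keep = tuple(c for c in full.classes if c.name in _PARCHMENT_CLASSES)
    return replace(full, classes=keep)


def _simulate_sample(
    rng: np.random.Generator,
    sample_id: str,
    spec: ClassSpec,
    peaks: Sequence[tuple[float, float, float]],
    baseline_sd: float,
    mz_range: tuple[float, float],
    temperature: float | None = None,
) -> PeakSpectrum:
    mz = np.array([p[0] for p in peaks])
    mean = np.array([p[1] for p in peaks])
    sd = np.array([p[2] for p in peaks]) * spec.dispersion
    inten = rng.normal(mean, np.where(sd > 0, sd, 1e-12))
    inten = inten + rng.normal(0.0, baseline_sd, size=inten.size)
    inten = np.clip(inten, 0.0, None)
    jitter = rng.normal(0.0, spec.mz_jitter_sd, size=mz.size)
    mz_j = np.clip(mz + jitter, mz_range[0], mz_range[1])
    order = np.argsort(mz_j, kind="stable")
    return PeakSpectrum(sample_id, spec.name, mz_j[order], inten[order], temperature)


def generate_dataset(config: SyntheticConfig, seed: int | None = None) -> list[PeakSpectrum]:
    """Generate one spectrum per sample; bit-identical for the same seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    spectra: list[PeakSpectrum] = []
    for spec in config.classes:
        peaks = config._class_peaks(spec)
        for i in range(spec.n_samples):
            spectra.append(
                _simulate_sample(
                    rng,
                    f"{spec.name}_{i:03d}",
                    spec,
                    peaks,
                    config.baseline_noise_sd,
                    config.mz_range,
                )
            )
    return spectra


def generate_temperature_dataset(
    config: SyntheticConfig,
    seed: int | None = None,
    levels: Sequence[float] | None = None,
) -> list[PeakSpectrum]:
    """Three-temperature dataset over the parchment classes.

    Per temperature level, the temperature-responsive classes (untreated and
    castor-oil-treated parchment) have their backbone means multiplied by the
    level's ``backbone_gain``, marker means by ``separation`` and dispersion
    by ``spread``; the glycerol-treated class is generated unmodified at all
    temperatures.  With the default levels this yields 69 + 78 + 85 = 232
    spectra.
    """
    config.validate()
    if not config.temperature_levels:
        raise ValueError("config has no temperature levels")
    chosen = list(config.temperature_levels)
    if levels is not None:
        by_temp = {lv.celsius: lv for lv in config.temperature_levels}
        missing = [t for t in levels if t not in by_temp]
        if missing:
            raise ValueError(f"unknown temperature level(s): {missing}")
        chosen = [by_temp[t] for t in levels]

    parch = [c for c in config.classes if c.name in _PARCHMENT_CLASSES]
    if len(parch) != 3:
        raise ValueError("config must contain the three parchment classes")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    spectra: list[PeakSpectrum] = []
    for level in chosen:
        counts = level.class_counts or tuple(c.n_samples for c in parch)
        if len(counts) != len(parch):
            raise ValueError("class_counts length must match parchment class count")
        for spec, n in zip(parch, counts):
            responsive = spec.name != "glycerol_parchment"
            backbone = config.shared_backbones.get(spec.backbone_id, ()) if spec.backbone_id else ()
            if responsive:
                peaks = [
                    (mz, mean * level.backbone_gain, sd) for mz, mean, sd in backbone
                ] + [
                    (mz, mean * level.separation, sd) for mz, mean, sd in spec.marker_peaks
                ]
                eff_spec = replace(spec, dispersion=spec.dispersion * level.spread)
            else:
                peaks = list(backbone) + list(spec.marker_peaks)
                eff_spec = spec
            peaks.sort(key=lambda p: p[0])
            for i in range(n):
                spectra.append(
                    _simulate_sample(
                        rng,
                        f"{spec.name}_T{level.celsius:g}_{i:03d}",
                        eff_spec,
                        peaks,
                        config.baseline_noise_sd,
                        config.mz_range,
                        temperature=level.celsius,
                    )
                )
    return spectra
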