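"""Synthetic NIR diffuse-reflectance spectra with planted origin signal.

The generator emulates the statistical structure of shell spectra from a
three-origin authentication study: a smooth absorbance background with
broad combination/overtone peaks, class-discriminative intensity
differences confined to two high-wavenumber bands (10,000-9500 and
9000-8500 cm^-1), per-sample multiplicative scatter and additive baseline
offsets (the distortion MSC is designed to invert), white instrument
noise, and three replicate scans per sample that are averaged into one
spectrum.

The three class-mean effect vectors are placed at equilateral positions
in the 2-D subspace spanned by the two band profiles, and their common
amplitude is calibrated so that the ideal (Bayes) classification accuracy
under the noise-only model equals a configurable target (default 0.95).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import multivariate_normal

from .grid import DEFAULT_GRID, WavenumberGrid

__all__ = [
    "SpectraSet",
    "SyntheticConfig",
    "generate_dataset",
    "average_replicates",
    "calibrate_class_effects",
    "bayes_accuracy",
    "DISCRIMINATIVE_BANDS",
    "ABDOMEN_PEAKS",
    "CARAPACE_PEAKS",
    "DEFAULT_CLASS_NAMES",
]

#: (high, low) wavenumber limits (cm^-1) of the two origin-discriminative bands.
DISCRIMINATIVE_BANDS: tuple[tuple[float, float], ...] = ((10_000.0, 9_500.0), (9_000.0, 8_500.0))

#: Prominent absorption peak centers (cm^-1) by body site.
ABDOMEN_PEAKS: tuple[float, ...] = (5_100.0, 7_000.0, 8_500.0)
CARAPACE_PEAKS: tuple[float, ...] = (5_200.0, 6_900.0, 8_400.0)

#: Origin classes: Weishan Lake, Tuo Lake, Hongze Lake.
DEFAULT_CLASS_NAMES: tuple[str, ...] = ("WL", "TL", "HL")

_SITES = ("abdomen", "carapace")


@dataclass
class SpectraSet:
    """A spectra matrix with its wavenumber axis and sample annotations."""

    grid: WavenumberGrid
    absorbance: np.ndarray  # (n_samples, n_wavelengths)
    labels: np.ndarray  # (n_samples,) class label per sample
    site: str
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        if self.absorbance.shape[1] != len(self.grid):
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the "
                f"grid has {len(self.grid)} points"
            )
        n = self.absorbance.shape[0]
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValueError("labels and sample_ids must match the number of rows")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if np.unique(self.labels).size < 2 and n > 0:
            # a single-class set is allowed for utility use, but flagged lazily
            pass

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, idx: Sequence[int]) -> "SpectraSet":
        idx = np.asarray(idx, dtype=int)
        return SpectraSet(
            grid=self.grid,
            absorbance=self.absorbance[idx],
            labels=self.labels[idx],
            site=self.site,
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic spectra generator.

    ``n_per_class`` may be a single count or one count per class (to mirror
    unbalanced designs).  ``class_band_effects`` maps each class to its two
    additive band amplitudes (absorbance units) on the discriminative
    bands; when ``None`` the amplitudes are auto-calibrated with
    :func:`calibrate_class_effects` so the ideal accuracy of the noise-only
    model equals ``bayes_target``.
    """

    n_per_class: int | Sequence[int] = 130
    class_names: Sequence[str] = DEFAULT_CLASS_NAMES
    site: str = "abdomen"
    peak_centers: Sequence[float] | None = None  # default depends on site
    peak_widths: Sequence[float] | None = None  # Gaussian sd, cm^-1
    peak_amplitudes: Sequence[float] = (0.50, 0.35, 0.30)
    class_band_effects: Mapping[str, tuple[float, float]] | None = None
    bands: tuple[tuple[float, float], ...] = DISCRIMINATIVE_BANDS
    scatter_sd: float = 0.05  # spread of the multiplicative factor m ~ N(1, sd)
    baseline_sd: float = 0.02  # absorbance units, additive offset a ~ N(0, sd)
    noise_sd: float = 0.10  # absorbance units, per-replicate within-origin noise
    n_replicates: int = 3
    bayes_target: float = 0.95
    seed: int = 0
    grid: WavenumberGrid = field(default_factory=lambda: DEFAULT_GRID)

    def __post_init__(self) -> None:
        if self.site not in _SITES:
            raise ValueError(f"site must be one of {_SITES}, got {self.site!r}")
        counts = self.per_class_counts()
        if any(c < 1 for c in counts):
            raise ValueError("n_per_class must be >= 1 for every class")
        for name, v in (
            ("scatter_sd", self.scatter_sd),
            ("baseline_sd", self.baseline_sd),
            ("noise_sd", self.noise_sd),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.peak_centers is None:
            self.peak_centers = ABDOMEN_PEAKS if self.site == "abdomen" else CARAPACE_PEAKS
        if self.peak_widths is None:
            self.peak_widths = (150.0,) * len(self.peak_centers)
        if len(self.peak_widths) != len(self.peak_centers):
            raise ValueError("peak_centers and peak_widths must have the same length")
        if len(self.peak_amplitudes) != len(self.peak_centers):
            raise ValueError("peak_amplitudes and peak_centers must have the same length")

    def per_class_counts(self) -> list[int]:
        if isinstance(self.n_per_class, int):
            return [self.n_per_class] * len(self.class_names)
        counts = [int(c) for c in self.n_per_class]
        if len(counts) != len(self.class_names):
            raise ValueError("n_per_class sequence must have one entry per class")
        return counts


def _band_profile(grid: WavenumberGrid, band: tuple[float, float]) -> np.ndarray:
    """Compact-support cos^2 bump, 1 at the band center, exactly 0 outside."""
    high, low = band
    center = 0.5 * (high + low)
    half_width = 0.5 * (high - low)
    u = (grid.values - center) / half_width
    profile = np.where(np.abs(u) < 1.0, np.cos(0.5 * np.pi * u) ** 2, 0.0)
    return profile


def bayes_accuracy(pairwise_distance: float, noise_sd: float) -> float:
    """Ideal accuracy for three equidistant Gaussian classes.

    The classes sit at the vertices of an equilateral triangle with side
    ``pairwise_distance`` in spectrum space, under isotropic noise with
    per-coordinate standard deviation ``noise_sd``.  The per-class correct
    probability is a bivariate-normal orthant probability with correlation
    cos(60 deg) = 1/2 at threshold d/(2 sigma).
    """
    if noise_sd <= 0:
        return 1.0
    h = pairwise_distance / (2.0 * noise_sd)
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, 0.5], [0.5, 1.0]])
    return float(mvn.cdf([h, h]))


def calibrate_class_effects(
    grid: WavenumberGrid,
    *,
    noise_sd: float,
    n_replicates: int = 3,
    bands: tuple[tuple[float, float], ...] = DISCRIMINATIVE_BANDS,
    class_names: Sequence[str] = DEFAULT_CLASS_NAMES,
    target_accuracy: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Band amplitudes giving a prescribed ideal accuracy.

    Places the three class means at equilateral positions in the plane
    spanned by the two (orthogonal, compact-support) band profiles and
    solves for the circumradius such that :func:`bayes_accuracy` equals
    ``target_accuracy`` under the replicate-averaged noise level
    ``noise_sd / sqrt(n_replicates)``.
    """
    if len(class_names) != 3:
        raise ValueError("calibration assumes exactly three classes")
    if len(bands) != 2:
        raise ValueError("calibration assumes exactly two discriminative bands")
    if not 1.0 / 3.0 < target_accuracy < 1.0:
        raise ValueError("target_accuracy must be in (1/3, 1)")
    sigma = noise_sd / math.sqrt(n_replicates)
    norms = [float(np.linalg.norm(_band_profile(grid, b))) for b in bands]
    if min(norms) == 0:
        raise ValueError("a discriminative band contains no grid points")
    if sigma == 0:
        d = 0.0
    else:
        h = brentq(
            lambda hh: bayes_accuracy(2.0 * hh, 1.0) - target_accuracy, 1e-6, 12.0
        )
        d = 2.0 * h * sigma
    radius = d / math.sqrt(3.0)
    angles = (0.5 * math.pi, 0.5 * math.pi + 2 * math.pi / 3, 0.5 * math.pi + 4 * math.pi / 3)
    return {
        name: (
            radius * math.cos(theta) / norms[0],
            radius * math.sin(theta) / norms[1],
        )
        for name, theta in zip(class_names, angles)
    }


def _clean_spectrum(config: SyntheticConfig) -> np.ndarray:
    """Class-independent absorbance background: ramp + broad Gaussian peaks."""
    nu = config.grid.values
    base = 0.40 + 0.20 * (config.grid.start - nu) / (config.grid.start - config.grid.end)
    for center, width, amp in zip(
        config.peak_centers, config.peak_widths, config.peak_amplitudes
    ):
        base = base + amp * np.exp(-0.5 * ((nu - center) / width) ** 2)
    return base


def generate_dataset(config: SyntheticConfig) -> SpectraSet:
    """Generate a labeled synthetic spectra set.

    Each sample is built as background + class band effects, distorted by a
    per-sample affine scatter model ``m * x + a`` with
    ``m ~ N(1, scatter_sd)`` and ``a ~ N(0, baseline_sd)``; each of its
    ``n_replicates`` replicate scans adds independent white noise, and the
    replicates are averaged into the sample's final spectrum.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    effects = config.class_band_effects
    if effects is None:
        effects = calibrate_class_effects(
            grid,
            noise_sd=config.noise_sd,
            n_replicates=config.n_replicates,
            bands=config.bands,
            class_names=config.class_names,
            target_accuracy=config.bayes_target,
        )
    profiles = [_band_profile(grid, b) for b in config.bands]
    background = _clean_spectrum(config)

    counts = config.per_class_counts()
    rows: list[np.ndarray] = []
    labels: list[str] = []
    sample_ids: list[str] = []
    for class_name, count in zip(config.class_names, counts):
        amps = effects.get(class_name, (0.0,) * len(profiles)) if effects else None
        clean = background.copy()
        if amps is not None:
            for amp, profile in zip(amps, profiles):
                clean = clean + amp * profile
        for i in range(count):
            m = 1.0 + config.scatter_sd * rng.standard_normal()
            a = config.baseline_sd * rng.standard_normal()
            replicates = (
                m * clean
                + a
                + config.noise_sd * rng.standard_normal((config.n_replicates, len(grid)))
            )
            rows.append(average_replicates(list(replicates)))
            labels.append(class_name)
            sample_ids.append(f"{config.site}-{class_name}-{i:03d}")
    return SpectraSet(
        grid=grid,
        absorbance=np.vstack(rows),
        labels=np.asarray(labels),
        site=config.site,
        sample_ids=sample_ids,
    )


def average_replicates(replicates: Sequence[np.ndarray]) -> np.ndarray:
    """Pointwise arithmetic mean of replicate scans of one sample.

    All replicates must lie on the same grid (equal length); the averaged
    spectrum represents the sample in downstream analysis.
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    arrays = [np.asarray(r, dtype=float) for r in replicates]
    length = arrays[0].shape
    for k, arr in enumerate(arrays):
        if arr.shape != length:
            raise ValueError(
                f"replicate {k} has shape {arr.shape}, expected {length}: "
                "replicates must share one grid"
            )
    return np.mean(arrays, axis=0)
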