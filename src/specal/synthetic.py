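"""Synthetic grass reflectance spectra.

Generates labeled visible–NIR datasets that mimic field-collected grass
canopy spectra: all classes share the landmark features of green vegetation
— the green-reflectance bump near 550 nm, the chlorophyll absorption trough
near 680 nm, the red-edge rise between roughly 690 and 750 nm, a broad NIR
plateau and the leaf-water dip near 970 nm — while the landmark amplitudes
vary per class.  Individual samples are then distorted by an affine scatter
model ``x -> a + b * x`` plus band-wise Gaussian noise, exactly the
distortion family that multiplicative scatter correction inverts.

The default geometry (15 classes x 50 samples, 125 bands on 400–1000 nm)
matches a typical portable line-scanning spectrometer campaign over a
multi-species grassland plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_io import SpectraSet

__all__ = [
    "ClassProfile",
    "ScatterModel",
    "make_class_profiles",
    "simulate_spectra",
    "make_benchmark",
    "DEFAULT_N_CLASSES",
    "DEFAULT_N_BANDS",
    "DEFAULT_N_PER_CLASS",
    "DEFAULT_WAVELENGTH_RANGE",
]

DEFAULT_N_CLASSES = 15
DEFAULT_N_BANDS = 125
DEFAULT_N_PER_CLASS = 50
DEFAULT_WAVELENGTH_RANGE = (400.0, 1000.0)

#: Default bound on the per-band first difference of a base curve.
SMOOTHNESS_BOUND = 0.05


@dataclass
class ClassProfile:
    """Noise-free reflectance curve of one grass class."""

    class_id: int
    wavelengths: np.ndarray
    base_curve: np.ndarray
    feature_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.base_curve = np.asarray(self.base_curve, dtype=float)
        if self.base_curve.shape != self.wavelengths.shape:
            raise ValueError("base_curve length must equal the band count")
        if self.base_curve.min() < 0 or self.base_curve.max() > 1:
            raise ValueError("base_curve values must lie in [0, 1]")


@dataclass
class ScatterModel:
    """Per-sample affine scatter distortion plus band-wise noise.

    A sample of class ``c`` is drawn as ``a + b * base_c + eps`` with
    ``a ~ Normal(0, additive_offset_sd)``,
    ``b ~ Uniform(*multiplicative_slope_range)`` and
    ``eps ~ Normal(0, noise_sd)`` i.i.d. per band.  Defaults emulate the
    moderate baseline drift and gain variation of field canopy measurements
    under natural light.
    """

    additive_offset_sd: float = 0.02
    multiplicative_slope_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.multiplicative_slope_range
        if lo <= 0 or hi <= 0:
            raise ValueError("multiplicative slopes must be strictly positive")
        if hi < lo:
            raise ValueError("multiplicative_slope_range must be (low, high)")
        if self.noise_sd < 0 or self.additive_offset_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _sigmoid(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wl - center) / width))


def _smooth_to_bound(curve: np.ndarray, bound: float) -> np.ndarray:
    """Repeated 3-point smoothing until the first difference is below bound.

    At coarse band spacings the red-edge slope can exceed the per-band
    smoothness bound; binomial smoothing in band space enforces it without
    leaving [0, 1].
    """
    for _ in range(200):
        if curve.size < 3 or np.max(np.abs(np.diff(curve))) < bound:
            break
        padded = np.concatenate([curve[:1], curve, curve[-1:]])
        curve = 0.25 * padded[:-2] + 0.5 * padded[1:-1] + 0.25 * padded[2:]
    return curve


def make_class_profiles(
    n_classes: int = DEFAULT_N_CLASSES,
    n_bands: int = DEFAULT_N_BANDS,
    wavelength_range: tuple[float, float] = DEFAULT_WAVELENGTH_RANGE,
    seed: int = 0,
    smoothness_bound: float = SMOOTHNESS_BOUND,
) -> list[ClassProfile]:
    """Build per-class smooth base reflectance curves.

    All classes share landmark positions (green bump, chlorophyll trough,
    red edge, NIR plateau, water dip); each class draws its own landmark
    amplitudes, which is what separates the classes.  Deterministic for a
    fixed seed.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    if n_bands < 8:
        raise ValueError("n_bands must be at least 8")
    lo, hi = wavelength_range
    if not hi > lo:
        raise ValueError("wavelength_range must be increasing (low, high)")

    wl = np.linspace(lo, hi, n_bands)
    rng = np.random.default_rng(seed)
    profiles = []
    for c in range(n_classes):
        params = {
            "visible_base": rng.uniform(0.03, 0.07),
            "green_amp": rng.uniform(0.03, 0.10),       # bump at 550 nm
            "trough_depth": rng.uniform(0.01, 0.05),    # absorption at 680 nm
            "nir_level": rng.uniform(0.30, 0.60),       # plateau beyond red edge
            "red_edge_center": 720.0,
            "red_edge_width": rng.uniform(12.0, 18.0),
            "water_dip_depth": rng.uniform(0.03, 0.12),  # dip at 970 nm
            "nir_tilt": rng.uniform(-0.05, 0.05),       # gentle plateau slope
        }
        base = params["visible_base"] * np.ones_like(wl)
        base = base + params["green_amp"] * _gaussian(wl, 550.0, 25.0)
        base = base - params["trough_depth"] * _gaussian(wl, 680.0, 15.0)
        rise = params["nir_level"] - params["visible_base"]
        edge = _sigmoid(wl, params["red_edge_center"], params["red_edge_width"])
        base = base + rise * edge
        base = base + params["nir_tilt"] * edge * (wl - 750.0) / 250.0
        base = base - params["water_dip_depth"] * _gaussian(wl, 970.0, 20.0)
        base = np.clip(base, 0.0, 1.0)
        base = _smooth_to_bound(base, smoothness_bound)
        profiles.append(ClassProfile(
            class_id=c,
            wavelengths=wl,
            base_curve=base,
            feature_params=params,
        ))
    return profiles


def simulate_spectra(
    profiles: list[ClassProfile],
    n_per_class: int = DEFAULT_N_PER_CLASS,
    scatter: ScatterModel | None = None,
    seed: int = 0,
) -> SpectraSet:
    """Draw labeled samples around each class profile under the scatter model.

    Sample order is class-major: sample ``i`` carries label
    ``i // n_per_class``.  Deterministic for a fixed seed.
    """
    if not profiles:
        raise ValueError("profiles must be a non-empty list")
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    scatter = scatter or ScatterModel()
    rng = np.random.default_rng(seed)
    wl = profiles[0].wavelengths
    n_bands = wl.size

    rows, labels = [], []
    for profile in profiles:
        a = rng.normal(0.0, scatter.additive_offset_sd, size=n_per_class)
        b = rng.uniform(*scatter.multiplicative_slope_range, size=n_per_class)
        eps = rng.normal(0.0, scatter.noise_sd, size=(n_per_class, n_bands))
        rows.append(a[:, None] + b[:, None] * profile.base_curve[None, :] + eps)
        labels.extend([profile.class_id] * n_per_class)
    return SpectraSet(
        wavelengths=wl,
        reflectance=np.vstack(rows),
        labels=np.asarray(labels),
    )


def make_benchmark(seed: int = 0,
                   scatter: ScatterModel | None = None) -> SpectraSet:
    """The default synthetic benchmark: 15 classes x 50 samples, 125 bands.

    Class profiles are drawn from the seed as well, so distinct seeds give
    independently drawn class geometries and sample noise.
    """
    profile_seed = int(np.random.SeedSequence([seed, 0]).generate_state(1)[0]
                       % 2**31)
    sample_seed = int(np.random.SeedSequence([seed, 1]).generate_state(1)[0]
                      % 2**31)
    profiles = make_class_profiles(seed=profile_seed)
    return simulate_spectra(profiles, scatter=scatter, seed=sample_seed)
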