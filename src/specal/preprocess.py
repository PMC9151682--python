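"""Scatter correction and moving-window smoothing (the "MS" stage).

Multiplicative scatter correction (MSC) regresses each spectrum on a
reference spectrum (by default the mean of the fitting set) and inverts the
fitted affine distortion, ``x_corr = (x - offset) / slope``.  This removes
baseline shifts and multiplicative gain effects caused by uneven canopy
surface, illumination and shadow.  A weighted moving-window mean over
``2n + 1`` bands then suppresses band-wise noise.  The two steps composed,
MSC first, form the multivariate-smoothing transform used ahead of the
manifold embedding.

Held-out spectra are always corrected against the *training* reference,
never their own mean, so no test information leaks into preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateReferenceError, DegenerateSampleError
from .spectra_io import SpectraSet

__all__ = [
    "MSCModel",
    "SmoothSpec",
    "msc_fit",
    "msc_apply",
    "moving_window_smooth",
    "ms_transform",
    "MSTransform",
]

_SLOPE_EPS = 1e-12


@dataclass
class MSCModel:
    """Fitted scatter-correction model: reference + per-sample affine pairs."""

    reference: np.ndarray
    offsets: np.ndarray   # per-sample baseline shift b_j
    slopes: np.ndarray    # per-sample multiplicative slope


@dataclass
class SmoothSpec:
    """A ``2n + 1``-band smoothing window.

    ``weights`` may be given explicitly (length ``2n + 1``, non-negative;
    normalized to sum to 1), or chosen by ``kind``: ``"uniform"`` (default)
    or ``"triangular"``.
    """

    half_width: int = 2
    weights: np.ndarray | None = None
    kind: str = "uniform"

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")
        width = 2 * self.half_width + 1
        if self.weights is None:
            if self.kind == "uniform":
                w = np.ones(width)
            elif self.kind == "triangular":
                w = self.half_width + 1.0 - np.abs(
                    np.arange(width) - self.half_width)
            else:
                raise ValueError(f"unknown window kind '{self.kind}'")
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (width,):
                raise ValueError(f"weights must have length {width}")
            if (w < 0).any():
                raise ValueError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        self.weights = w / total


def _ols_affine(x: np.ndarray, reference: np.ndarray) -> tuple[float, float]:
    """Least-squares (offset, slope) of ``x ~ offset + slope * reference``."""
    ref_c = reference - reference.mean()
    var = float(ref_c @ ref_c)
    slope = float(ref_c @ (x - x.mean())) / var
    offset = float(x.mean() - slope * reference.mean())
    return offset, slope


def _resolve_reference(spectra, reference):
    X = spectra.reflectance if isinstance(spectra, SpectraSet) else np.atleast_2d(
        np.asarray(spectra, dtype=float))
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError("reference must be 'mean' or a spectrum")
        ref = X.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise ValueError("reference length must equal band count")
    if np.ptp(ref) == 0 or float((ref - ref.mean()) @ (ref - ref.mean())) < _SLOPE_EPS:
        raise DegenerateReferenceError("reference spectrum has zero variance")
    return X, ref


def msc_fit(spectra, reference="mean") -> MSCModel:
    """Fit per-sample affine regressions against a reference spectrum.

    Parameters
    ----------
    spectra : SpectraSet or (n_samples, n_bands) array.
    reference : ``"mean"`` (per-band mean of the fitting set) or an explicit
        spectrum, e.g. a training-set mean when fitting held-out data.
    """
    X, ref = _resolve_reference(spectra, reference)
    offsets = np.empty(X.shape[0])
    slopes = np.empty(X.shape[0])
    for i, x in enumerate(X):
        offsets[i], slopes[i] = _ols_affine(x, ref)
        if abs(slopes[i]) < _SLOPE_EPS:
            raise DegenerateSampleError(
                f"sample {i}: fitted slope {slopes[i]:.3g} is numerically zero")
    return MSCModel(reference=ref, offsets=offsets, slopes=slopes)


def msc_apply(model: MSCModel, spectra) -> SpectraSet | np.ndarray:
    """Scatter-correct spectra against the model's reference.

    Each sample is regressed on the stored reference and inverted with its
    own fitted pair, ``(x - offset) / slope`` — so previously unseen spectra
    are corrected against the training reference.  Returns the same type it
    was given (SpectraSet in, SpectraSet out).
    """
    X = spectra.reflectance if isinstance(spectra, SpectraSet) else np.atleast_2d(
        np.asarray(spectra, dtype=float))
    if X.shape[1] != model.reference.size:
        raise ValueError("band count does not match fitted reference")
    corrected = np.empty_like(X, dtype=float)
    for i, x in enumerate(X):
        offset, slope = _ols_affine(x, model.reference)
        if abs(slope) < _SLOPE_EPS:
            raise DegenerateSampleError(
                f"sample {i}: fitted slope {slope:.3g} is numerically zero")
        corrected[i] = (x - offset) / slope
    if isinstance(spectra, SpectraSet):
        return spectra.with_reflectance(corrected)
    return corrected


def moving_window_smooth(spectra, spec: SmoothSpec | None = None):
    """Weighted running mean over a ``2n + 1``-band window.

    Edge bands use the part of the window that fits, with the weights
    renormalized over it (no reflectance is invented beyond the measured
    range).  Constants are preserved everywhere.
    """
    spec = spec or SmoothSpec()
    X = spectra.reflectance if isinstance(spectra, SpectraSet) else np.atleast_2d(
        np.asarray(spectra, dtype=float))
    n = spec.half_width
    width = 2 * n + 1
    n_bands = X.shape[1]
    if width > n_bands:
        raise ValueError(
            f"window width {width} exceeds band count {n_bands}")
    out = np.empty_like(X, dtype=float)
    for k in range(n_bands):
        j_lo = max(0, k - n)
        j_hi = min(n_bands - 1, k + n)
        w = spec.weights[(j_lo - k + n):(j_hi - k + n + 1)]
        w = w / w.sum()
        out[:, k] = X[:, j_lo:j_hi + 1] @ w
    if isinstance(spectra, SpectraSet):
        return spectra.with_reflectance(out)
    return out


@dataclass
class MSTransform:
    """Fitted MSC-then-smooth transform, reusable on held-out spectra."""

    smooth: SmoothSpec = field(default_factory=SmoothSpec)
    msc_model: MSCModel | None = None

    def fit_transform(self, spectra):
        model = msc_fit(spectra, reference="mean")
        self.msc_model = MSCModel(reference=model.reference,
                                  offsets=model.offsets, slopes=model.slopes)
        return moving_window_smooth(msc_apply(model, spectra), self.smooth)

    def transform(self, spectra):
        if self.msc_model is None:
            raise ValueError("transform called before fit_transform")
        return moving_window_smooth(
            msc_apply(self.msc_model, spectra), self.smooth)


def ms_transform(spectra, smooth: SmoothSpec | None = None):
    """One-shot multivariate smoothing: MSC (mean reference) then smoothing.

    Returns ``(transformed, fitted MSTransform)``; the fitted transform
    carries the training reference for held-out spectra.
    """
    transform = MSTransform(smooth=smooth or SmoothSpec())
    out = transform.fit_transform(spectra)
    return out, transform
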