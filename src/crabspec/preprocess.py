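"""Spectral pretreatments: MSC, SNV and Savitzky-Golay smoothing.

MSC regresses each spectrum on a reference (the training-set mean) and
inverts the fitted affine distortion; SNV standardizes each spectrum to
zero mean and unit variance; SG smoothing runs a moving local polynomial
fit.  The MSC reference is fit on training rows only and reused for test
rows, so no test information leaks into the correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["MSCReference", "fit_msc_reference", "msc", "snv", "savitzky_golay"]


@dataclass(frozen=True)
class MSCReference:
    """Reference spectrum for multiplicative scatter correction."""

    reference_spectrum: np.ndarray
    source: str = "train_mean"  # "train_mean" | "supplied"

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_spectrum, dtype=float)
        if ref.ndim != 1:
            raise ValueError("reference spectrum must be 1-D")
        if not np.all(np.isfinite(ref)):
            raise ValueError("reference spectrum must be finite")
        object.__setattr__(self, "reference_spectrum", ref)


def fit_msc_reference(X_train: np.ndarray) -> MSCReference:
    """Columnwise mean of the training spectra as MSC reference.

    Requires at least two training spectra: a single spectrum would make
    the 'mean reference' that spectrum itself and the correction vacuous.
    """
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_msc_reference needs a matrix with >= 2 training spectra")
    return MSCReference(reference_spectrum=X.mean(axis=0), source="train_mean")


def msc(X: np.ndarray, ref: MSCReference) -> np.ndarray:
    """Multiplicative scatter correction against a fitted reference.

    For each row x, ordinary least squares fits ``x ~ a + b * ref`` and
    returns ``(x - a) / b``, undoing an affine scatter distortion exactly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r = ref.reference_spectrum
    if X.shape[1] != r.size:
        raise ValueError(f"spectra have {X.shape[1]} points, reference has {r.size}")
    rc = r - r.mean()
    denom = float(rc @ rc)
    if denom == 0.0:
        raise ValueError("MSC reference is constant; slope undefined")
    Xc = X - X.mean(axis=1, keepdims=True)
    slopes = (Xc @ rc) / denom
    bad = np.nonzero(np.abs(slopes) < 1e-12)[0]
    if bad.size:
        raise ValueError(
            f"MSC slope is ~0 for rows {bad.tolist()}: spectra uncorrelated "
            "with the reference cannot be corrected"
        )
    intercepts = X.mean(axis=1) - slopes * r.mean()
    return (X - intercepts[:, None]) / slopes[:, None]


def snv(X: np.ndarray, sample_ids: Sequence[str] | None = None) -> np.ndarray:
    """Standard normal variate: per-row standardization to mean 0, sd 1.

    The sample (n-1) standard deviation is used.  Constant rows have no
    scale and raise, naming the offending sample when ids are supplied.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least two points per spectrum")
    sd = X.std(axis=1, ddof=1)
    bad = np.nonzero(sd == 0.0)[0]
    if bad.size:
        names = (
            [sample_ids[i] for i in bad] if sample_ids is not None else bad.tolist()
        )
        raise ValueError(f"SNV undefined for constant spectra: {names}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def savitzky_golay(X: np.ndarray, window: int = 15, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing (0th derivative) along each spectrum.

    Mirror padding handles the edges, so polynomials of degree <=
    ``polyorder`` pass through unchanged in the interior.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0 or window <= polyorder:
        raise ValueError(
            f"window must be odd and > polyorder, got window={window}, polyorder={polyorder}"
        )
    if window > X.shape[1]:
        raise ValueError(f"window {window} exceeds spectrum length {X.shape[1]}")
    return savgol_filter(X, window_length=window, polyorder=polyorder, axis=1, mode="mirror")
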