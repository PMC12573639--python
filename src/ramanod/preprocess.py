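"""Detector correction, wavenumber calibration and SVD noise reduction.

Raw spectra are divided by the (max-normalized) white-light response of
the detector, the pixel axis is mapped to wavenumbers by a polynomial
fitted to indene reference peaks, and noise is reduced by truncated
singular-value reconstruction of the cell-by-wavenumber matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import SpectrumSet


class WhiteLightCorrector(BaseEstimator, TransformerMixin):
    """Divide every spectrum by the max-normalized detector response.

    Parameters
    ----------
    response : ndarray of shape (n_bins,)
        Strictly positive white-light spectrum over detector pixels.
    """

    def __init__(self, response: np.ndarray):
        self.response = response

    def fit(self, X=None, y=None):
        response = np.asarray(self.response, dtype=float)
        if response.ndim != 1:
            raise ValueError("white-light response must be 1-D")
        if np.any(response <= 0):
            raise ValueError("white-light response must be strictly positive")
        self.response_ = response / response.max()
        return self

    def transform(self, X):
        if not hasattr(self, "response_"):
            self.fit()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.response_.size:
            raise ValueError(
                f"spectra have {X.shape[1]} bins but response has {self.response_.size}"
            )
        return X / self.response_[None, :]


def white_light_correct(raw: SpectrumSet, white_light: np.ndarray) -> SpectrumSet:
    """Detector-sensitivity correction of a :class:`SpectrumSet`."""
    corrected = WhiteLightCorrector(white_light).fit().transform(raw.intensity)
    return replace(raw, intensity=corrected, metadata=raw.metadata.copy())


def calibrate_wavenumber(
    pixel_axis: np.ndarray,
    indene_peaks: list[tuple[float, float]],
    degree: int = 3,
):
    """Polynomial pixel-to-wavenumber calibration against indene peaks.

    Parameters
    ----------
    pixel_axis : ndarray
        Detector pixel positions to map.
    indene_peaks : list of (pixel_position, reference_wavenumber)
        Measured peak pixel positions paired with the reference Raman
        shifts of indene.
    degree : int, default=3
        Degree of the least-squares polynomial; needs at least
        ``degree + 1`` peak pairs.

    Returns
    -------
    axis : ndarray
        Fitted wavenumber for every pixel.
    residuals : ndarray
        Reference minus fitted wavenumber at each peak.
    """
    pixel_axis = np.asarray(pixel_axis, dtype=float)
    pairs = np.asarray(indene_peaks, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("indene_peaks must be (pixel, wavenumber) pairs")
    px, wn = pairs[:, 0], pairs[:, 1]
    if len(np.unique(px)) != len(px):
        raise ValueError("peak pixel positions must be distinct")
    if len(px) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} peak pairs for degree {degree}, got {len(px)}"
        )
    coeffs = np.polynomial.polynomial.polyfit(px, wn, degree)
    fitted_peaks = np.polynomial.polynomial.polyval(px, coeffs)
    axis = np.polynomial.polynomial.polyval(pixel_axis, coeffs)
    if np.any(np.diff(axis) <= 0):
        raise ValueError("calibration error: fitted axis is not strictly increasing")
    return axis, wn - fitted_peaks


@dataclass
class SVDReport:
    singular_values: np.ndarray
    n_keep: int
    variance_kept: float


class SVDDenoiser(BaseEstimator, TransformerMixin):
    """Truncated-SVD reconstruction of the spectra matrix.

    ``n_keep='auto'`` keeps the smallest rank whose singular values
    retain at least ``variance_threshold`` of the total squared
    spectral energy.
    """

    def __init__(self, n_keep: int | str = "auto", variance_threshold: float = 0.99):
        self.n_keep = n_keep
        self.variance_threshold = variance_threshold

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        total = float(np.sum(s**2))
        frac = np.cumsum(s**2) / total if total > 0 else np.ones_like(s)
        if self.n_keep == "auto":
            k = int(np.searchsorted(frac, self.variance_threshold) + 1)
        else:
            k = int(self.n_keep)
            if not 1 <= k <= min(X.shape):
                raise ValueError(
                    f"n_keep={k} outside [1, {min(X.shape)}] for a {X.shape} matrix"
                )
        self.singular_values_ = s
        self.n_keep_ = k
        self.variance_kept_ = float(frac[k - 1])
        self.components_ = Vt[:k]
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X @ self.components_.T) @ self.components_

    def report(self) -> SVDReport:
        return SVDReport(self.singular_values_, self.n_keep_, self.variance_kept_)


def svd_denoise(spectra: SpectrumSet, n_keep: int | str = "auto"):
    """Rank-truncated reconstruction of a :class:`SpectrumSet`.

    Returns the denoised set and an :class:`SVDReport` with the
    retained singular values and variance fraction.
    """
    den = SVDDenoiser(n_keep=n_keep)
    den.fit(spectra.intensity)
    out = replace(
        spectra,
        intensity=den.transform(spectra.intensity),
        metadata=spectra.metadata.copy(),
    )
    return out, den.report()
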