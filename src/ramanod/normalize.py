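"""Water OH-stretch standardization of component intensity profiles.

Absolute single-cell Raman intensities depend on acquisition geometry
and focus, so per-cell component intensities are divided by the area of
the water OH-stretch band (3150-3700 cm^-1), fitted as a sum of three
Gaussians.  The water content of the probed volume acts as an internal
intensity standard: scaling a cell's whole spectrum by a constant
leaves its standardized profile unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import ConcentrationProfile, SpectrumSet

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (3150.0, 3700.0)
# Deterministic initialization: three centers spread over the window,
# common width, amplitudes read from the window thirds.
_INIT_CENTERS = (3280.0, 3450.0, 3610.0)
_INIT_SIGMA = 60.0


def _three_gaussians(x, a1, c1, s1, a2, c2, s2, a3, c3, s3):
    return (
        a1 * np.exp(-0.5 * ((x - c1) / s1) ** 2)
        + a2 * np.exp(-0.5 * ((x - c2) / s2) ** 2)
        + a3 * np.exp(-0.5 * ((x - c3) / s3) ** 2)
    )


@dataclass
class WaterBandFit:
    """Three-Gaussian fit of the OH-stretch band of one cell."""

    amplitudes: np.ndarray
    centers: np.ndarray
    sigmas: np.ndarray
    total_area: float
    fit_rss: float
    success: bool

    @property
    def params(self) -> np.ndarray:
        return np.column_stack([self.amplitudes, self.centers, self.sigmas])


def fit_water_band(
    spectrum: np.ndarray,
    axis: np.ndarray,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> WaterBandFit:
    """Fit three Gaussians to the water band and return its analytic area.

    The total area is the closed-form sum ``sum(a_i * sigma_i * sqrt(2 pi))``.
    If the bounded least-squares fit fails, ``success`` is False and the
    area falls back to the trapezoidal integral over the window.
    """
    axis = np.asarray(axis, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float).ravel()
    lo, hi = window
    if lo < axis[0] or hi > axis[-1]:
        raise ValueError(f"window [{lo}, {hi}] outside axis range")
    mask = (axis >= lo) & (axis <= hi)
    if mask.sum() < 20:
        raise ValueError("need at least 20 bins inside the water window")
    x, y = axis[mask], spectrum[mask]

    thirds = np.array_split(np.arange(x.size), 3)
    amp0 = [max(float(y[idx].max()), 1e-12) for idx in thirds]
    p0 = []
    for a, c in zip(amp0, _INIT_CENTERS):
        p0 += [a, c, _INIT_SIGMA]
    lower = [0.0, lo, 5.0] * 3
    upper = [np.inf, hi, 400.0] * 3
    try:
        popt, _ = curve_fit(
            _three_gaussians, x, y, p0=p0, bounds=(lower, upper), maxfev=5000
        )
        resid = y - _three_gaussians(x, *popt)
        params = np.asarray(popt).reshape(3, 3)
        amps, centers, sigmas = params[:, 0], params[:, 1], params[:, 2]
        area = float(np.sum(amps * sigmas * np.sqrt(2.0 * np.pi)))
        return WaterBandFit(
            amplitudes=amps,
            centers=centers,
            sigmas=sigmas,
            total_area=area,
            fit_rss=float(np.sum(resid**2)),
            success=True,
        )
    except RuntimeError:
        area = float(np.trapezoid(np.clip(y, 0.0, None), x))
        logger.warning(
            "water-band fit failed; falling back to trapezoidal area %.4g", area
        )
        return WaterBandFit(
            amplitudes=np.zeros(3),
            centers=np.asarray(_INIT_CENTERS),
            sigmas=np.full(3, _INIT_SIGMA),
            total_area=area,
            fit_rss=float("nan"),
            success=False,
        )


def water_areas(
    spectra: SpectrumSet, window: tuple[float, float] = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Per-cell water-band areas (audit table with fit status)."""
    rows = []
    for i in range(spectra.n_cells):
        fit = fit_water_band(spectra.intensity[i], spectra.axis, window)
        rows.append(
            {
                "cell_id": spectra.metadata["cell_id"].iloc[i],
                "water_area": fit.total_area,
                "fit_success": fit.success,
                "fit_rss": fit.fit_rss,
            }
        )
    return pd.DataFrame(rows)


def standardize_profiles(
    profile: ConcentrationProfile, areas: pd.DataFrame | np.ndarray
) -> ConcentrationProfile:
    """Divide every cell's component intensities by its water-band area.

    Cells with non-positive areas are excluded (logged); fallback-area
    cells are flagged.  Refuses to run on an already standardized
    profile.
    """
    if profile.standardized:
        raise ValueError("profile is already water-standardized")
    if isinstance(areas, pd.DataFrame):
        table = areas.set_index("cell_id")
        order = profile.metadata["cell_id"]
        missing = [c for c in order if c not in table.index]
        if missing:
            raise ValueError(f"no water area for cells: {missing[:5]}")
        values = table.loc[order, "water_area"].to_numpy(dtype=float)
        success = (
            table.loc[order, "fit_success"].to_numpy(dtype=bool)
            if "fit_success" in table.columns
            else np.ones(len(order), dtype=bool)
        )
    else:
        values = np.asarray(areas, dtype=float).ravel()
        success = np.ones(values.size, dtype=bool)
    if values.size != profile.n_cells:
        raise ValueError("one water area per cell is required")

    keep = values > 0
    if not keep.all():
        dropped = profile.metadata.loc[~keep, "cell_id"].tolist()
        logger.warning("excluding %d cells with non-positive water area: %s",
                       len(dropped), dropped[:5])
    out_values = profile.values[keep] / values[keep, None]
    meta = profile.metadata.loc[keep].reset_index(drop=True)
    flags = pd.DataFrame(
        {"cell_id": meta["cell_id"], "water_fit_fallback": ~success[keep]}
    )
    return ConcentrationProfile(
        values=out_values,
        components=list(profile.components),
        metadata=meta,
        standardized=True,
        flags=flags,
    )


class WaterBandNormalizer(BaseEstimator, TransformerMixin):
    """Estimator form of water-band standardization.

    ``fit`` takes the :class:`SpectrumSet` (or an intensity matrix with
    ``axis=``) whose water bands define the per-cell areas; ``transform``
    divides a cell-by-component intensity matrix by those areas.
    """

    def __init__(self, window: tuple[float, float] = DEFAULT_WINDOW):
        self.window = window

    def fit(self, X, y=None, axis: np.ndarray | None = None):
        if isinstance(X, SpectrumSet):
            table = water_areas(X, self.window)
            self.areas_ = table["water_area"].to_numpy()
            self.fit_success_ = table["fit_success"].to_numpy()
        else:
            if axis is None:
                raise ValueError("axis= is required when X is a bare matrix")
            X = np.atleast_2d(np.asarray(X, dtype=float))
            fits = [fit_water_band(row, axis, self.window) for row in X]
            self.areas_ = np.array([f.total_area for f in fits])
            self.fit_success_ = np.array([f.success for f in fits])
        return self

    def transform(self, H):
        if not hasattr(self, "areas_"):
            raise RuntimeError("WaterBandNormalizer is not fitted")
        H = np.atleast_2d(np.asarray(H, dtype=float))
        if H.shape[0] != self.areas_.size:
            raise ValueError("row count does not match fitted water areas")
        if np.any(self.areas_ <= 0):
            raise ValueError("non-positive water areas present; use standardize_profiles")
        return H / self.areas_[:, None]
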