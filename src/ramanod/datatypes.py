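"""Core in-memory containers shared across the pipeline.

The central objects mirror the bilinear model of Raman unmixing,
``A = H W + E``: a :class:`SpectrumSet` holds the cell-by-wavenumber
matrix ``A`` with per-cell metadata, a :class:`ComponentSet` holds the
component spectra ``W`` and a :class:`ConcentrationProfile` holds the
per-cell component intensities ``H``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("cell_id", "nodule_id", "phase", "size_group")


def _validate_axis(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size == 0:
        raise ValueError("wavenumber axis must be a non-empty 1-D array")
    if not np.all(np.diff(axis) > 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    return axis


@dataclass
class SpectrumSet:
    """Cell-by-wavenumber intensity matrix with per-cell metadata.

    Parameters
    ----------
    axis : ndarray of shape (n_bins,)
        Strictly increasing wavenumber axis in cm^-1.
    intensity : ndarray of shape (n_cells, n_bins)
        Raman intensities (counts; may be negative after detector
        correction, clipping is applied only where a stage requires it).
    metadata : DataFrame
        One row per cell with at least the columns
        ``cell_id, nodule_id, phase, size_group``.  ``cell_id`` must be
        unique.
    """

    axis: np.ndarray
    intensity: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.axis = _validate_axis(self.axis)
        self.intensity = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        if self.intensity.shape[1] != self.axis.size:
            raise ValueError(
                f"intensity has {self.intensity.shape[1]} columns but axis has "
                f"{self.axis.size} bins"
            )
        if len(self.metadata) != self.intensity.shape[0]:
            raise ValueError("metadata row count does not match intensity rows")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValueError(f"metadata is missing columns: {missing}")
        dup = self.metadata["cell_id"].duplicated()
        if dup.any():
            bad = self.metadata.loc[dup, "cell_id"].iloc[0]
            raise ValueError(f"duplicate cell_id: {bad!r}")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_bins(self) -> int:
        return self.axis.size

    def crop(self, lo: float, hi: float) -> "SpectrumSet":
        """Restrict to wavenumbers in the closed interval [lo, hi]."""
        mask = (self.axis >= lo) & (self.axis <= hi)
        if not mask.any():
            raise ValueError(f"no bins inside [{lo}, {hi}] cm^-1")
        return replace(
            self,
            axis=self.axis[mask],
            intensity=self.intensity[:, mask],
            metadata=self.metadata.copy(),
        )

    def copy(self) -> "SpectrumSet":
        return replace(
            self,
            axis=self.axis.copy(),
            intensity=self.intensity.copy(),
            metadata=self.metadata.copy(),
        )


@dataclass
class ComponentSet:
    """Component-by-wavenumber spectra (the matrix ``W``) with labels."""

    axis: np.ndarray
    spectra: np.ndarray
    names: list[str]
    band_annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = _validate_axis(self.axis)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.names = list(self.names)
        if self.spectra.shape != (len(self.names), self.axis.size):
            raise ValueError(
                f"spectra shape {self.spectra.shape} does not match "
                f"({len(self.names)} names, {self.axis.size} bins)"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("component names must be unique")
        if np.any(self.spectra < 0):
            raise ValueError("component spectra must be non-negative")

    @property
    def n_components(self) -> int:
        return len(self.names)

    def crop(self, lo: float, hi: float) -> "ComponentSet":
        mask = (self.axis >= lo) & (self.axis <= hi)
        if not mask.any():
            raise ValueError(f"no bins inside [{lo}, {hi}] cm^-1")
        return ComponentSet(
            axis=self.axis[mask],
            spectra=self.spectra[:, mask],
            names=list(self.names),
            band_annotations=dict(self.band_annotations),
        )


@dataclass
class ConcentrationProfile:
    """Cell-by-component intensity matrix (the matrix ``H``).

    ``standardized`` records whether rows have been divided by the
    per-cell water-band area; the normalization stage refuses to apply
    itself twice.
    """

    values: np.ndarray
    components: list[str]
    metadata: pd.DataFrame
    standardized: bool = False
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.components = list(self.components)
        if self.values.shape[1] != len(self.components):
            raise ValueError("values column count does not match component names")
        if len(self.metadata) != self.values.shape[0]:
            raise ValueError("metadata row count does not match values rows")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.components)
        return pd.concat([self.metadata.reset_index(drop=True), frame], axis=1)


ARA_COLUMNS = ("phase", "size_group", "replicate_id", "ara_total", "ara_per_weight", "nodule_weight")


def validate_ara_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check an ARA table for the required columns and value ranges."""
    missing = [c for c in ARA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ARA table is missing columns: {missing}")
    if (table["ara_total"] < 0).any() or (table["ara_per_weight"] < 0).any():
        raise ValueError("ARA values must be non-negative")
    if (table["nodule_weight"] <= 0).any():
        raise ValueError("nodule weights must be positive")
    return table
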