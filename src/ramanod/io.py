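"""Readers and writers for the pipeline's tabular and HDF5 layouts.

Spectra travel as wide CSV tables (metadata columns followed by one
column per wavenumber, UTF-8, comma-separated, header row) or as an
HDF5 container with datasets ``/axis``, ``/intensity``, ``/metadata``
and optional ground truth under ``/truth``.  Component spectra,
intensity profiles and ARA tables are plain CSV; model reports and
manifests are JSON.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .datatypes import METADATA_COLUMNS, ComponentSet, ConcentrationProfile, SpectrumSet, validate_ara_table


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Spectrum tables (CSV)

def write_spectrum_table(spectra: SpectrumSet, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(spectra.intensity, columns=[f"{w:g}" for w in spectra.axis])
    out = pd.concat([spectra.metadata.reset_index(drop=True), frame], axis=1)
    out.to_csv(path, index=False)
    return path


def read_spectrum_table(path: str | Path) -> SpectrumSet:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    meta_cols = [c for c in METADATA_COLUMNS if c in frame.columns]
    if len(meta_cols) != len(METADATA_COLUMNS):
        missing = set(METADATA_COLUMNS) - set(meta_cols)
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    wn_cols = [c for c in frame.columns if c not in METADATA_COLUMNS]
    try:
        axis = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavenumber column header: {exc}") from exc
    if np.any(np.diff(axis) <= 0):
        raise FormatError(f"{path}: wavenumber columns are not strictly increasing")
    dup = frame["cell_id"].duplicated()
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2  # header + 1-based
        raise FormatError(
            f"{path}:{line}: duplicate cell_id {frame.loc[dup, 'cell_id'].iloc[0]!r}"
        )
    intensity = frame[wn_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(intensity)):
        row = int(np.argwhere(~np.isfinite(intensity))[0, 0]) + 2
        raise FormatError(f"{path}:{row}: non-finite intensity value")
    return SpectrumSet(axis=axis, intensity=intensity, metadata=frame[list(METADATA_COLUMNS)])


# ---------------------------------------------------------------------------
# HDF5 cohort container

def write_cohort_h5(
    spectra: SpectrumSet,
    path: str | Path,
    truth_W: ComponentSet | None = None,
    truth_H: ConcentrationProfile | None = None,
) -> Path:
    path = Path(path)
    meta = spectra.metadata
    with h5py.File(path, "w") as f:
        f.create_dataset("axis", data=spectra.axis, track_times=False)
        f.create_dataset("intensity", data=spectra.intensity, track_times=False)
        grp = f.create_group("metadata")
        for col in METADATA_COLUMNS:
            grp.create_dataset(
                col,
                data=np.array(meta[col].astype(str).tolist(), dtype="S"),
                track_times=False,
            )
        if truth_W is not None:
            f.create_dataset("truth/W", data=truth_W.spectra, track_times=False)
            f.create_dataset(
                "truth/W_names",
                data=np.array(truth_W.names, dtype="S"),
                track_times=False,
            )
        if truth_H is not None:
            f.create_dataset("truth/H", data=truth_H.values, track_times=False)
    return path


def read_cohort_h5(path: str | Path):
    """Return (SpectrumSet, truth_W or None, truth_H or None)."""
    with h5py.File(path, "r") as f:
        axis = f["axis"][:]
        intensity = f["intensity"][:]
        meta = pd.DataFrame(
            {col: [v.decode() for v in f["metadata"][col][:]] for col in METADATA_COLUMNS}
        )
        spectra = SpectrumSet(axis=axis, intensity=intensity, metadata=meta)
        truth_W = truth_H = None
        if "truth" in f:
            if "W" in f["truth"]:
                names = [v.decode() for v in f["truth/W_names"][:]]
                truth_W = ComponentSet(axis=axis, spectra=f["truth/W"][:], names=names)
            if "H" in f["truth"]:
                comps = truth_W.names if truth_W is not None else [
                    f"c{i}" for i in range(f["truth/H"].shape[1])
                ]
                truth_H = ConcentrationProfile(
                    values=f["truth/H"][:], components=comps, metadata=meta.copy()
                )
    return spectra, truth_W, truth_H


# ---------------------------------------------------------------------------
# Components, profiles, ARA tables

def write_components(components: ComponentSet, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(components.spectra, columns=[f"{w:g}" for w in components.axis])
    frame.insert(0, "component", components.names)
    frame.to_csv(path, index=False)
    return path


def read_components(path: str | Path) -> ComponentSet:
    frame = pd.read_csv(path)
    names = frame["component"].tolist()
    wn_cols = [c for c in frame.columns if c != "component"]
    axis = np.array([float(c) for c in wn_cols])
    return ComponentSet(axis=axis, spectra=frame[wn_cols].to_numpy(dtype=float), names=names)


def write_profile(profile: ConcentrationProfile, path: str | Path) -> Path:
    path = Path(path)
    frame = profile.to_frame()
    frame["standardized"] = profile.standardized
    frame.to_csv(path, index=False)
    return path


def read_profile(path: str | Path) -> ConcentrationProfile:
    frame = pd.read_csv(path)
    std = bool(frame["standardized"].iloc[0]) if "standardized" in frame.columns else False
    comps = [
        c for c in frame.columns if c not in METADATA_COLUMNS and c != "standardized"
    ]
    return ConcentrationProfile(
        values=frame[comps].to_numpy(dtype=float),
        components=comps,
        metadata=frame[list(METADATA_COLUMNS)],
        standardized=std,
    )


def write_ara_table(ara: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_ara_table(ara).to_csv(path, index=False)
    return path


def read_ara_table(path: str | Path) -> pd.DataFrame:
    return validate_ara_table(pd.read_csv(path))


# ---------------------------------------------------------------------------
# JSON reports

class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(data: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(data, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")
    return path


def load_indene_reference() -> dict:
    """Shipped indene calibration reference (shifts in cm^-1 and degree)."""
    text = resources.files("ramanod.data").joinpath("indene_reference.yaml").read_text()
    return yaml.safe_load(text)
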