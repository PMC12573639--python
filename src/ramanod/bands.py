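"""Raman band tables for the six bacteroid biomolecular components.

Band centers follow the published assignments for nodule bacteroids:
protein (phenylalanine/tryptophan ring breathing at 1004 cm^-1, amide
III, C-H bending, amide I), the storage polymer PHB (ester C=O at
1736 cm^-1 among others), cytochrome, DNA, an aromatic metabolite and
an ester lipid.  Relative amplitudes and widths are free parameters of
the simulator; the defaults below are chosen to give each component a
realistic, distinct fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np


class Band(NamedTuple):
    center: float  # cm^-1
    amplitude: float  # relative, dimensionless
    width: float  # Gaussian sigma, cm^-1


@dataclass
class BandTable:
    """Ordered list of Raman bands for one biomolecular component."""

    component_name: str
    bands: list[Band] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bands = [Band(*b) for b in self.bands]
        centers = [b.center for b in self.bands]
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("band centers must be strictly increasing")
        if any(b.amplitude <= 0 for b in self.bands):
            raise ValueError("band amplitudes must be positive")
        if any(b.width <= 0 for b in self.bands):
            raise ValueError("band widths must be positive")

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands], dtype=float)


def _table(name: str, rows: list[tuple[float, float, float]]) -> BandTable:
    return BandTable(name, [Band(*r) for r in rows])


#: Default six-component library: (center cm^-1, relative amplitude, sigma cm^-1).
DEFAULT_BAND_TABLES: dict[str, BandTable] = {
    "protein": _table(
        "protein",
        [(1004, 1.00, 8), (1250, 0.55, 14), (1451, 0.65, 12), (1661, 0.85, 14)],
    ),
    "PHB": _table(
        "PHB",
        [
            (834, 0.45, 10),
            (902, 0.35, 10),
            (1058, 0.50, 10),
            (1104, 0.40, 10),
            (1352, 0.45, 10),
            (1455, 0.60, 10),
            (1736, 1.00, 10),
        ],
    ),
    "cytochrome": _table(
        "cytochrome",
        [(747, 0.80, 9), (1126, 0.60, 9), (1304, 0.50, 10), (1332, 0.55, 10), (1583, 1.00, 10)],
    ),
    "DNA": _table(
        "DNA",
        [
            (684, 0.35, 10),
            (785, 1.00, 10),
            (1095, 0.60, 12),
            (1364, 0.35, 9),
            (1374, 0.35, 9),
            (1488, 0.50, 10),
            (1577, 0.55, 10),
        ],
    ),
    "metabolite": _table(
        "metabolite",
        [(1001, 1.00, 14), (1445, 0.70, 16)],
    ),
    "lipid": _table(
        "lipid",
        [(1091, 0.50, 12), (1443, 1.00, 12), (1655, 0.70, 12), (1738, 0.80, 10)],
    ),
}

COMPONENT_ORDER = ("protein", "PHB", "cytochrome", "DNA", "metabolite", "lipid")
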