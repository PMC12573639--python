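"""Synthetic single-cell Raman cohorts with matched nitrogen-fixation tables.

The study design emulated here: soybean nodules sampled at three growth
phases (nodulation ``Nod``, flowering ``Flo``, ripening ``Rip``), nine
nodules per phase split over three size groups (``G1`` < 1.5 mm,
``G2`` 1.5-2.0 mm, ``G3`` > 2.0 mm), and 29-32 single bacteroid cells
measured per nodule (~828 cells).  Each cell's spectrum is a
non-negative mixture of six biomolecular component spectra (protein,
PHB, cytochrome, DNA, aromatic metabolite, lipid) plus a broad water
OH-stretch band, a slowly varying baseline and detector noise.

Acetylene-reduction (ARA) activity is simulated per pot replicate and
per nodule from the component content through a positive-weighted
linear model dominated by PHB, with a planted nodule-size effect, so
that the downstream regression and testing stages have a known ground
truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import BandTable, COMPONENT_ORDER, DEFAULT_BAND_TABLES
from .datatypes import ComponentSet, ConcentrationProfile, SpectrumSet, validate_ara_table

PHASES = ("Nod", "Flo", "Rip")
SIZE_GROUPS = ("G1", "G2", "G3")

#: Water OH-stretch band model: (relative amplitude, center cm^-1, sigma cm^-1).
WATER_BAND_SHAPE = ((1.0, 3250.0, 60.0), (0.6, 3420.0, 50.0), (0.3, 3600.0, 40.0))

# Per-phase mean concentrations (arbitrary concentration units) and
# per-size-group multipliers.  PHB rises through the growth phases and
# with nodule size; cytochrome follows the same trend less markedly;
# DNA declines weakly; protein fluctuates without a trend; metabolite
# and lipid stay flat.
_PHASE_BASE = {
    "protein": (1.00, 0.90, 1.05),
    "PHB": (0.40, 0.90, 1.10),
    "cytochrome": (0.50, 0.65, 0.75),
    "DNA": (0.80, 0.72, 0.65),
    "metabolite": (0.30, 0.30, 0.30),
    "lipid": (0.45, 0.45, 0.45),
}
_SIZE_MULT = {
    "protein": (1.0, 1.0, 1.0),
    "PHB": (0.8, 1.0, 1.2),
    "cytochrome": (0.95, 1.0, 1.05),
    "DNA": (1.0, 1.0, 1.0),
    "metabolite": (1.0, 1.0, 1.0),
    "lipid": (1.0, 1.0, 1.0),
}
# Cell-to-cell coefficient of variation; storage/metabolite pools are
# the most heterogeneous across single cells.
_CELL_CV = {
    "protein": 0.30,
    "PHB": 0.50,
    "cytochrome": 0.35,
    "DNA": 0.30,
    "metabolite": 0.50,
    "lipid": 0.40,
}

_NODULE_WEIGHT_MG = {"G1": 2.0, "G2": 5.0, "G3": 10.0}


def default_concentration_means() -> pd.DataFrame:
    """Mean component concentration for every (phase, size_group) cell population."""
    rows = {}
    for pi, phase in enumerate(PHASES):
        for si, size in enumerate(SIZE_GROUPS):
            rows[(phase, size)] = {
                c: _PHASE_BASE[c][pi] * _SIZE_MULT[c][si] for c in COMPONENT_ORDER
            }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["phase", "size_group"])
    return frame[list(COMPONENT_ORDER)]


@dataclass
class ConcentrationModel:
    """Per-(phase, size) mean vectors and per-component dispersion (CV)."""

    means: pd.DataFrame = field(default_factory=default_concentration_means)
    cv: dict = field(default_factory=lambda: dict(_CELL_CV))

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.cv.values()):
            raise ValueError("dispersions must be >= 0")

    @property
    def components(self) -> list[str]:
        return list(self.means.columns)


@dataclass
class NoiseModel:
    """Spectral nuisance model.

    snr
        Peak signal-to-noise ratio; noise variance is
        intensity-proportional (shot-like) plus a constant readout term,
        scaled so the standard deviation at the mean fingerprint peak
        equals peak/snr.  ``inf`` disables noise.
    baseline_amplitude
        Mean residual baseline level as a fraction of the mean
        fingerprint peak (random non-negative polynomial per cell).
    water_peak
        Water OH-stretch peak height as a multiple of the mean
        fingerprint peak; per-cell amplitude drawn uniformly from
        ``water_amplitude_range`` times this.
    """

    snr: float = 20.0
    baseline_order: int = 2
    baseline_amplitude: float = 0.02
    water_peak: float = 1.0
    water_amplitude_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.baseline_amplitude < 0 or self.water_peak < 0:
            raise ValueError("noise amplitudes must be >= 0")
        lo, hi = self.water_amplitude_range
        if lo < 0 or hi < lo:
            raise ValueError("water_amplitude_range must be 0 <= lo <= hi")

    @classmethod
    def silent(cls) -> "NoiseModel":
        """Noise-free configuration: spectra equal H_true @ W_true exactly."""
        return cls(snr=np.inf, baseline_amplitude=0.0, water_peak=0.0)


@dataclass
class AraModel:
    """Linear ARA response: positive weights on component content plus a
    size-group offset and Gaussian noise, truncated at zero.

    The default plants a nodule-size effect of about three
    within-condition standard deviations between G3 and G1 (PHB term
    plus offset), matching the reported size dependence of
    nitrogen-fixation activity.
    """

    weights: dict = field(
        default_factory=lambda: {"PHB": 6.0, "cytochrome": 0.5}
    )
    size_offsets: dict = field(default_factory=lambda: {"G1": 0.0, "G2": 0.12, "G3": 0.24})
    noise_sd: float = 0.4
    replicate_cv: float = 0.03
    n_replicates: int = 4

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("at least 2 replicates are required for group tests")

    def response(self, profile: pd.Series | dict, size_group: str) -> float:
        """Noise-free ARA response for one mean component profile."""
        total = sum(w * float(profile[c]) for c, w in self.weights.items())
        return total + self.size_offsets.get(size_group, 0.0)


@dataclass
class CohortDesign:
    """Full description of one simulated cohort."""

    phases: tuple = PHASES
    size_groups: tuple = SIZE_GROUPS
    nodules_per_phase: int = 9
    cells_per_nodule: tuple[int, int] = (29, 32)
    axis_start: float = 600.0
    axis_stop: float = 3800.0
    axis_step: float = 2.0
    band_tables: dict = field(default_factory=lambda: dict(DEFAULT_BAND_TABLES))
    concentration_model: ConcentrationModel = field(default_factory=ConcentrationModel)
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    ara_model: AraModel = field(default_factory=AraModel)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cells_per_nodule
        if not (1 <= lo <= hi <= 10000):
            raise ValueError("cells_per_nodule bounds must satisfy 1 <= lo <= hi <= 10000")
        if self.nodules_per_phase < 1:
            raise ValueError("nodules_per_phase must be >= 1")

    @property
    def axis(self) -> np.ndarray:
        n = int(round((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)

    @property
    def n_samples(self) -> int:
        return self.nodules_per_phase * len(self.phases)


@dataclass
class GeneratedCohort:
    """Ground-truth container: spectra plus everything that made them."""

    spectra: SpectrumSet
    true_components: ComponentSet
    true_profile: ConcentrationProfile
    ara: pd.DataFrame
    nodule_ara: pd.DataFrame
    design: CohortDesign


def make_pure_spectrum(band_table: BandTable, axis: np.ndarray) -> np.ndarray:
    """Sum of Gaussian bands, normalized to unit trapezoidal area.

    An empty band table yields the all-zero vector (area normalization
    is skipped in that case).
    """
    axis = np.asarray(axis, dtype=float)
    if axis.size == 0:
        raise ValueError("axis must be non-empty")
    if not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly increasing")
    if not band_table.bands:
        return np.zeros_like(axis)
    centers = band_table.centers
    if centers.min() < axis[0] or centers.max() > axis[-1]:
        raise ValueError(
            f"band center outside axis range [{axis[0]}, {axis[-1]}] "
            f"for component {band_table.component_name!r}"
        )
    spectrum = np.zeros_like(axis)
    for band in band_table.bands:
        spectrum += band.amplitude * np.exp(-0.5 * ((axis - band.center) / band.width) ** 2)
    area = np.trapezoid(spectrum, axis)
    return spectrum / area


def component_library(design: CohortDesign) -> ComponentSet:
    """Pure-component spectra for a design, in canonical component order."""
    axis = design.axis
    names = [n for n in COMPONENT_ORDER if n in design.band_tables]
    names += [n for n in design.band_tables if n not in names]
    spectra = np.vstack([make_pure_spectrum(design.band_tables[n], axis) for n in names])
    return ComponentSet(
        axis=axis, spectra=spectra, names=names, band_annotations=dict(design.band_tables)
    )


def water_band_profile(axis: np.ndarray) -> np.ndarray:
    """Three-Gaussian OH-stretch shape (3150-3700 cm^-1), unit peak height."""
    axis = np.asarray(axis, dtype=float)
    shape = np.zeros_like(axis)
    for amp, center, sigma in WATER_BAND_SHAPE:
        shape += amp * np.exp(-0.5 * ((axis - center) / sigma) ** 2)
    peak = shape.max()
    return shape / peak if peak > 0 else shape


def simulate_cohort(design: CohortDesign | None = None, seed: int | None = None) -> GeneratedCohort:
    """Draw a full labeled cohort from a design.

    The same design and seed always produce the identical cohort.  With
    :meth:`NoiseModel.silent` the intensity matrix equals
    ``H_true @ W_true`` exactly.
    """
    design = design if design is not None else CohortDesign()
    if seed is not None:
        design = replace(design, seed=seed)
    rng = np.random.default_rng(design.seed)
    axis = design.axis
    library = component_library(design)
    comps = library.names
    means = design.concentration_model.means
    cvs = design.concentration_model.cv

    meta_rows: list[dict] = []
    conc_rows: list[np.ndarray] = []
    nodule_units: list[dict] = []
    lo, hi = design.cells_per_nodule
    for phase in design.phases:
        for j in range(design.nodules_per_phase):
            size = design.size_groups[j % len(design.size_groups)]
            nodule_id = f"{phase}-n{j + 1:02d}"
            n_cells = int(rng.integers(lo, hi + 1))
            mu = means.loc[(phase, size)].reindex(comps).to_numpy()
            sd = np.array([cvs.get(c, 0.0) for c in comps]) * mu
            draws = np.clip(rng.normal(mu, sd, size=(n_cells, len(comps))), 0.0, None)
            conc_rows.append(draws)
            nodule_units.append(
                {
                    "phase": phase,
                    "size_group": size,
                    "nodule_id": nodule_id,
                    **{c: m for c, m in zip(comps, draws.mean(axis=0))},
                }
            )
            for k in range(n_cells):
                meta_rows.append(
                    {
                        "cell_id": f"{nodule_id}-c{k + 1:03d}",
                        "nodule_id": nodule_id,
                        "phase": phase,
                        "size_group": size,
                    }
                )
    H_true = np.vstack(conc_rows)
    metadata = pd.DataFrame(meta_rows)
    clean = H_true @ library.spectra

    nm = design.noise_model
    ref = float(clean.max(axis=1).mean()) if clean.size else 0.0
    intensity = clean.copy()
    n_cells_total = intensity.shape[0]

    if nm.baseline_amplitude > 0 and ref > 0:
        x = np.linspace(0.0, 1.0, axis.size)
        powers = np.vstack([x**k for k in range(nm.baseline_order + 1)])
        coeffs = rng.uniform(0.0, 1.0, size=(n_cells_total, nm.baseline_order + 1))
        baseline = coeffs @ powers
        baseline *= (nm.baseline_amplitude * ref) / baseline.mean(axis=1, keepdims=True)
        intensity += baseline

    if nm.water_peak > 0 and ref > 0:
        shape = water_band_profile(axis)
        lo_a, hi_a = nm.water_amplitude_range
        scales = nm.water_peak * ref * rng.uniform(lo_a, hi_a, size=n_cells_total)
        intensity += scales[:, None] * shape[None, :]

    if np.isfinite(nm.snr) and ref > 0:
        peak_var = (ref / nm.snr) ** 2
        a = 0.9 * peak_var / ref
        b = 0.1 * peak_var
        sd = np.sqrt(a * np.clip(intensity, 0.0, None) + b)
        intensity = intensity + rng.normal(0.0, 1.0, size=intensity.shape) * sd
        np.clip(intensity, 0.0, None, out=intensity)

    spectra = SpectrumSet(axis=axis, intensity=intensity, metadata=metadata)
    profile = ConcentrationProfile(values=H_true, components=comps, metadata=metadata.copy())

    # Pot-level ARA table (4 replicates per condition) and per-nodule ARA.
    ara_seed = int(rng.integers(0, 2**31 - 1))
    unit_profiles = replicate_mean_profiles(design, seed=ara_seed)
    ara = simulate_ara(unit_profiles, design.ara_model, seed=ara_seed + 1)
    nodule_frame = pd.DataFrame(nodule_units).rename(columns={"nodule_id": "replicate_id"})
    nodule_ara = simulate_ara(
        nodule_frame, design.ara_model, seed=ara_seed + 2, min_replicates=1
    )

    return GeneratedCohort(
        spectra=spectra,
        true_components=library,
        true_profile=profile,
        ara=ara,
        nodule_ara=nodule_ara,
        design=design,
    )


def replicate_mean_profiles(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Mean component profile per (phase, size, pot replicate) unit.

    Each pot pools many nodules, so its mean profile is the condition
    mean jittered by a small replicate-level CV.
    """
    rng = np.random.default_rng(seed)
    model = design.ara_model
    means = design.concentration_model.means
    comps = design.concentration_model.components
    rows = []
    for phase in design.phases:
        for size in design.size_groups:
            mu = means.loc[(phase, size)].to_numpy()
            for rep in range(1, model.n_replicates + 1):
                jitter = 1.0 + model.replicate_cv * rng.normal(size=len(comps))
                prof = np.clip(mu * jitter, 0.0, None)
                rows.append(
                    {
                        "phase": phase,
                        "size_group": size,
                        "replicate_id": f"rep{rep}",
                        **{c: v for c, v in zip(comps, prof)},
                    }
                )
    return pd.DataFrame(rows)


def simulate_ara(
    unit_profiles: pd.DataFrame,
    ara_model: AraModel | None = None,
    seed: int = 0,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """ARA table from mean component profiles, one row per measurement unit.

    ``unit_profiles`` must carry ``phase``, ``size_group``,
    ``replicate_id`` and one column per component the model weights.
    Values are the linear response plus Gaussian noise, truncated at 0.
    """
    model = ara_model if ara_model is not None else AraModel()
    required = {"phase", "size_group", "replicate_id"}
    missing = required - set(unit_profiles.columns)
    if missing:
        raise ValueError(f"unit_profiles is missing columns: {sorted(missing)}")
    counts = unit_profiles.groupby(["phase", "size_group"]).size()
    if (counts < min_replicates).any():
        raise ValueError(
            f"each (phase, size_group) condition needs >= {min_replicates} replicates"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for _, unit in unit_profiles.iterrows():
        signal = model.response(unit, unit["size_group"])
        value = max(signal + rng.normal(0.0, model.noise_sd), 0.0)
        weight = _NODULE_WEIGHT_MG.get(unit["size_group"], 5.0) * (
            1.0 + 0.1 * rng.normal()
        )
        weight = max(weight, 0.1)
        rows.append(
            {
                "phase": unit["phase"],
                "size_group": unit["size_group"],
                "replicate_id": unit["replicate_id"],
                "ara_total": value,
                "ara_per_weight": value / weight,
                "nodule_weight": weight,
            }
        )
    return validate_ara_table(pd.DataFrame(rows))
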