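"""End-to-end pipeline driver: simulate -> denoise -> unmix -> standardize -> stats.

A :class:`PipelineConfig` fixes every stage parameter and seed; running
the same config twice reproduces byte-identical artifacts, recorded in
a manifest of SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .datatypes import ComponentSet, ConcentrationProfile
from .io import (
    write_ara_table,
    write_components,
    write_json,
    write_profile,
    write_spectrum_table,
)
from .mcr import MCRALS, match_components
from .normalize import standardize_profiles, water_areas
from .preprocess import svd_denoise
from .stats_ml import aggregate_profiles, group_ttest, pca_scores, rfr_train_eval
from .synthetic import CohortDesign, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage toggle, parameter and seed of one pipeline run."""

    seed: int = 0
    # stage toggles
    simulate: bool = True
    denoise: bool = True
    unmix: bool = True
    normalize: bool = True
    stats: bool = True
    # simulate
    nodules_per_phase: int = 9
    cells_per_nodule: tuple[int, int] = (29, 32)
    snr: float = 20.0
    # preprocess
    svd_keep: int | str = "auto"
    # mcr
    n_components: int = 6
    alpha_l1_h: float = 5e-05
    mcr_init: str = "purest_variable"
    mcr_window: tuple[float, float] = (600.0, 1800.0)
    max_iter: int = 500
    tol: float = 1e-06
    # normalize
    water_window: tuple[float, float] = (3150.0, 3700.0)
    # stats
    cv_folds: int = 5
    train_fraction: float = 0.75
    ara_target: str = "ara_total"
    aggregation_level: str = "condition"
    ttest_contrast: tuple[str, str] = ("G3", "G1")
    ttest_phase: str = "Nod"

    def __post_init__(self) -> None:
        if self.alpha_l1_h <= 0:
            raise ValueError("alpha_l1_h must be > 0")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("cells_per_nodule", "mcr_window", "water_window", "ttest_contrast"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def design(self) -> CohortDesign:
        design = CohortDesign(
            nodules_per_phase=self.nodules_per_phase,
            cells_per_nodule=tuple(self.cells_per_nodule),
            seed=self.seed,
        )
        design.noise_model.snr = self.snr
        return design


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in order; return the result summary.

    Writes stage artifacts plus ``manifest.json`` (config hash, package
    version, seeds, per-file checksums) into ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    results: dict = {"config_hash": config.config_hash()}

    if not config.simulate:
        raise ValueError("run_pipeline currently requires simulate=True (no input path given)")

    logger.info("stage=simulate seed=%d", config.seed)
    cohort = simulate_cohort(config.design())
    artifacts["spectra"] = write_spectrum_table(cohort.spectra, outdir / "spectra.csv")
    artifacts["truth_W"] = write_components(cohort.true_components, outdir / "truth_W.csv")
    artifacts["truth_H"] = write_profile(cohort.true_profile, outdir / "truth_H.csv")
    artifacts["ara"] = write_ara_table(cohort.ara, outdir / "ara.csv")
    artifacts["nodule_ara"] = write_ara_table(cohort.nodule_ara, outdir / "nodule_ara.csv")
    results["n_cells"] = cohort.spectra.n_cells
    spectra = cohort.spectra

    profile = None
    resolved = None
    if config.unmix:
        # Crop to the unmixing window before denoising: the SVD rank is
        # chosen from the variance structure of the matrix being
        # factored, not of the water-dominated full axis.
        fp = spectra.crop(*config.mcr_window)
        if config.denoise:
            fp, svd_report = svd_denoise(fp, n_keep=config.svd_keep)
            logger.info(
                "stage=denoise n_keep=%d variance_kept=%.6f",
                svd_report.n_keep,
                svd_report.variance_kept,
            )
            results["svd"] = {
                "n_keep": svd_report.n_keep,
                "variance_kept": svd_report.variance_kept,
            }
        est = MCRALS(
            n_components=config.n_components,
            alpha_l1_h=config.alpha_l1_h,
            init=config.mcr_init,
            max_iter=config.max_iter,
            tol=config.tol,
            random_state=config.seed,
        )
        H = est.fit_transform(fp.intensity)
        resolved = ComponentSet(
            axis=fp.axis,
            spectra=est.components_,
            names=[f"component_{i + 1}" for i in range(config.n_components)],
        )
        truth_fp = cohort.true_components.crop(*config.mcr_window)
        mapping, _, _ = match_components(resolved, truth_fp)
        named = [mapping[n][0] if n in mapping else n for n in resolved.names]
        if len(set(named)) == len(named):
            resolved.names = named
        profile = ConcentrationProfile(
            values=H,
            components=list(resolved.names),
            metadata=spectra.metadata.copy(),
        )
        artifacts["W"] = write_components(resolved, outdir / "W.csv")
        artifacts["H"] = write_profile(profile, outdir / "H.csv")
        write_json(
            {
                "alpha_l1_h": est.alpha_l1_h,
                "n_iter": est.n_iter_,
                "converged": est.converged_,
                "residual_norm": est.reconstruction_err_,
                "init": est.init,
                "seed": est.random_state,
                "match": {k: {"reference": v[0], "cosine": v[1]} for k, v in mapping.items()},
            },
            outdir / "mcr_model.json",
        )
        artifacts["mcr_model"] = outdir / "mcr_model.json"
        results["mcr"] = {"n_iter": est.n_iter_, "converged": est.converged_}

    if config.normalize and profile is not None:
        areas = water_areas(cohort.spectra, window=tuple(config.water_window))
        areas.to_csv(outdir / "water_areas.csv", index=False)
        artifacts["water_areas"] = outdir / "water_areas.csv"
        profile = standardize_profiles(profile, areas)
        artifacts["H_std"] = write_profile(profile, outdir / "H_std.csv")

    if config.stats and profile is not None:
        pca = pca_scores(profile, group_by="size_group")
        write_json(
            {
                g: {
                    "explained_variance_ratio": r.explained_variance_ratio,
                    "loadings": r.loadings,
                    "feature_names": r.feature_names,
                }
                for g, r in pca.items()
            },
            outdir / "pca.json",
        )
        artifacts["pca"] = outdir / "pca.json"

        agg = aggregate_profiles(profile, level=config.aggregation_level)
        if config.aggregation_level == "nodule":
            # one observation per nodule, each with its own simulated ARA
            ara = cohort.nodule_ara.set_index("replicate_id")
            merged = agg.copy()
            merged[config.ara_target] = ara.loc[
                merged["nodule_id"], config.ara_target
            ].to_numpy()
        else:
            # one observation per pot replicate: condition-mean profile
            # paired with that pot's ARA measurement
            merged = cohort.ara.merge(agg, on=["phase", "size_group"])
        reports = {}
        for group in sorted(merged["size_group"].unique()):
            sub = merged[merged["size_group"] == group]
            report = rfr_train_eval(
                sub,
                sub[config.ara_target],
                size_group=group,
                feature_names=list(profile.components),
                cv_folds=config.cv_folds,
                train_fraction=config.train_fraction,
                seed=config.seed,
                stratify=sub["phase"] if "phase" in sub.columns else None,
            )
            reports[group] = report.to_dict()
        write_json(reports, outdir / "model_reports.json")
        artifacts["model_reports"] = outdir / "model_reports.json"
        results["model_reports"] = reports

        ttest = group_ttest(
            cohort.ara, contrast=tuple(config.ttest_contrast), within=config.ttest_phase
        )
        write_json(
            {
                "contrast": list(config.ttest_contrast),
                "phase": config.ttest_phase,
                "t": ttest.statistic,
                "df": ttest.df,
                "pvalue": ttest.pvalue,
            },
            outdir / "ttest.json",
        )
        artifacts["ttest"] = outdir / "ttest.json"
        results["ttest_pvalue"] = ttest.pvalue

    from . import __version__ as version

    manifest = {
        "version": version,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "checksums": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    write_json(manifest, outdir / "manifest.json")
    results["manifest"] = manifest
    return results
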