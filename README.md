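# ramanod

Single-cell Raman spectroscopic profiling of soybean-nodule **bacteroids**
— the differentiated, nitrogen-fixing form of rhizobia — and its link to
symbiotic nitrogen-fixation activity measured by the acetylene-reduction
assay (ARA).

The package implements the full analysis chain for cohorts of single-cell
Raman spectra collected across plant growth phases (nodulation `Nod`,
flowering `Flo`, ripening `Rip`) and nodule-size groups (`G1` < 1.5 mm,
`G2` 1.5–2.0 mm, `G3` > 2.0 mm):

1. **Preprocessing** — white-light detector-sensitivity correction,
   polynomial wavenumber calibration against indene reference peaks, and
   truncated-SVD noise reduction of the cell-by-wavenumber matrix.
2. **MCR-ALS unmixing** — the spectra matrix `A` (cells × wavenumbers) is
   factored as `A = H W + E` with non-negative component spectra `W`
   (rows unit-normalized) and intensity profiles `H`, by alternating
   exact non-negative least squares with an L1 (LASSO) penalty
   `α‖H‖₁` (default `α = 5e-05` under unit-max scaling of `A`) to
   discourage overfitted dense profiles. Six biomolecular components are
   resolved by default: protein, PHB (polyhydroxybutyrate), cytochrome,
   DNA, an aromatic metabolite, and an ester lipid.
3. **Water-band standardization** — each cell's profile row is divided by
   the area of its water OH-stretch band, fitted as three Gaussians over
   3150–3700 cm⁻¹, making profiles invariant to acquisition intensity.
4. **Statistics / ML** — per-size-group PCA of the standardized profiles;
   random-forest regression (RFR) of ARA with grid-searched
   hyperparameters (5-fold CV on a 75 % training split, held-out R² on
   the remaining 25 %) and impurity-based feature importances; Welch
   t-tests for nodule-size contrasts of ARA.

Because no raw spectra are publicly deposited for this system, the package
ships a first-class **synthetic cohort generator** that reproduces the
study design — 27 nodule samples (nine per phase over three size groups),
29–32 cells each, ≈ 830 cells — with pure component spectra built from
published Raman band positions (e.g. phenylalanine ring breathing at
1004 cm⁻¹ for protein; 834, 902, 1058, 1104, 1352, 1455 and 1736 cm⁻¹
for PHB), a planted PHB increase across growth phases and nodule sizes,
and a PHB-dominated ARA response. Every pipeline stage is tested against
this ground truth.

## Worked example

```bash
cat > design.yaml <<EOF
seed: 0
nodules_per_phase: 3
cells_per_nodule: [5, 7]
EOF
ramanod run --config design.yaml --out demo/
```

prints (small 54-cell demo cohort):

```
G1: test R^2 = 0.860
G2: test R^2 = 0.927
G3: test R^2 = 0.858
manifest: demo/manifest.json
```

and writes per-stage artifacts: the simulated spectra and ground truth,
resolved component spectra `W.csv`, intensity profiles `H.csv`, their
water-standardized form `H_std.csv`, per-group PCA results, RFR model
reports (chosen hyperparameters, held-out R², importances,
predicted-vs-actual pairs) and the Welch t-test of the planted
nodule-size effect — here `t = 4.17`, `p = 0.0091` for G3 vs G1 within
the Nod phase, i.e. larger nodules show significantly higher ARA. The
`manifest.json` records the config hash and SHA-256 checksums of every
artifact; rerunning the same config reproduces them byte-for-byte.

The same stages are available as a library of scikit-learn-style
estimators (`MCRALS`, `SVDDenoiser`, `WaterBandNormalizer`, `ARAForest`)
and as individual CLI subcommands
(`simulate`, `preprocess`, `unmix`, `normalize`, `pca`, `predict`, `run`).

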