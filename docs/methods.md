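# Methods

## The problem

Bacteroids — rhizobia differentiated inside legume nodule symbiosomes —
fix atmospheric nitrogen for the host plant. Single-cell Raman
microspectroscopy reads out their biomolecular composition label-free;
the acetylene-reduction assay (ARA) quantifies nitrogenase activity per
pot of nodules. This package links the two: it resolves per-cell
biomolecular profiles from Raman spectra and asks which constituents
predict nitrogen-fixation activity across growth phases (Nod/Flo/Rip)
and nodule-size groups (G1/G2/G3).

## Bilinear unmixing model

Preprocessed spectra form the non-negative matrix `A` (cells × bins).
MCR-ALS factors

    A = H W + E,      W ≥ 0, H ≥ 0,

with `W` (components × bins) the component spectra and `H` (cells ×
components) the per-cell intensities. The fit minimizes

    ½‖A − H W‖²_F + α‖H‖₁,

alternating two exact non-negative least-squares subproblems solved by
active-set NNLS on Cholesky-reduced normal equations (the Gram matrix is
only components × components, so ~830 cells and ~600 bins solve in
seconds). Because each half-step is an exact minimizer, the penalized
objective is non-increasing across iterations; the objective trace is
stored for audit.

Conventions and choices:

- **Non-negativity on both factors.** Standard for Raman MCR; resolved
  spectra and intensities are physically non-negative.
- **L1 penalty on H only**, default `α = 5e-05`. The absolute count
  scale of a detector is arbitrary, so `A` is internally scaled to unit
  maximum intensity before fitting; `α` is defined at that scale and `H`
  is rescaled back afterwards. This makes the penalty's meaning
  reproducible across instruments.
- **Scale convention.** After every iteration each row of `W` is scaled
  to unit L2 norm with the scale absorbed into `H`; the product `H W` is
  invariant to this renormalization.
- **Initialization.** Default `purest_variable`: a SIMPLISMA-style
  selection of the purest single-cell spectra — purity
  `std/(mean + offset)` per row, successive picks down-weighted by the
  determinant of the correlation-around-origin matrix with already
  selected rows, ties broken to the lowest index for determinism.
  `kmeans`, `random` and `user` initializations are also available.
- **Convergence.** Relative change of the residual Frobenius norm below
  `1e-06`, at most 500 iterations. On strongly denoised matrices the
  residual keeps creeping below that threshold for a long time; the
  model is then returned with `converged=False` and a warning, which in
  practice does not affect recovery quality.
- **Negative intensities** produced by detector correction are kept
  through preprocessing and clipped to zero only at the MCR input, to
  avoid biasing the noise statistics earlier.
- **Spectral window.** Unmixing runs on the fingerprint window
  600–1800 cm⁻¹ by default. The six target components have all their
  bands there, while the broad water OH-stretch band (3150–3700 cm⁻¹)
  would otherwise act as a dominant seventh source and absorb one of the
  six components. For the same reason the SVD denoising rank is chosen
  from the variance spectrum of the cropped matrix that is actually
  factored: on the full axis the water band dominates total variance
  and the 99 % rule under-ranks the fingerprint structure.

Resolved components are identified against reference spectra by cosine
similarity with optimal one-to-one Hungarian assignment; permutation and
scale are the only ambiguities of the factorization at low noise, so all
recovery scores are computed after matching.

## Preprocessing

- **White-light correction** divides each spectrum by the max-normalized
  detector response (strictly positive required).
- **Wavenumber calibration** fits a least-squares polynomial (default
  degree 3, a common spectrograph dispersion model) mapping pixel to
  cm⁻¹ through measured indene peak positions; the shipped
  `indene_reference.yaml` lists the reference shifts. The fit requires
  at least degree + 1 distinct peaks and rejects non-monotone solutions.
- **SVD denoising** reconstructs the matrix at a truncated rank;
  `n_keep='auto'` keeps the smallest rank retaining ≥ 99 % of squared
  spectral energy (conservative and reproducible; overridable).

## Water-band standardization

Absolute single-cell intensities depend on focus and acquisition
geometry. Each cell's water OH-stretch band is fitted between 3150 and
3700 cm⁻¹ as a sum of three Gaussians (deterministic initialization:
centers 3280/3450/3610 cm⁻¹, σ = 60 cm⁻¹, amplitudes from the window
thirds' maxima; bounded parameters), and the profile row is divided by
the analytic band area `Σ aᵢσᵢ√(2π)`. "Standardization" is read as this
area division only — no z-scoring is applied before PCA or regression;
PCA applies per-feature centering internally. If the fit fails the area
falls back to the trapezoidal integral over the window and the cell is
flagged; non-positive areas exclude the cell with a logged reason. A
provenance flag prevents double application.

## Synthetic cohorts

The generator emulates the study design: 3 growth phases × 9 nodules
(3 per size group), 29–32 cells per nodule drawn uniformly (only the
range is known), wavenumber axis 600–3800 cm⁻¹ at 2 cm⁻¹ so that both
the fingerprint and the water region live on one grid.

- **Component spectra**: Gaussian bands (default σ = 10 cm⁻¹ unless set
  per band) at the published centers for protein, PHB, cytochrome, DNA,
  aromatic metabolite and lipid, each normalized to unit area. Only the
  band *centers* are published; relative amplitudes and widths are free
  parameters with documented defaults.
- **Concentrations**: per-(phase, size) means with truncated-normal
  cell-to-cell variation (CV 0.30–0.50; storage and metabolite pools the
  most heterogeneous, consistent with wide single-cell distributions).
  Planted effects: PHB mean rises Nod < Flo ≤ Rip and with nodule size;
  cytochrome follows weakly; DNA declines weakly with phase; protein
  fluctuates; metabolite and lipid stay flat.
- **Nuisance terms**: a random non-negative residual baseline polynomial
  (order 2, mean level 2 % of the mean fingerprint peak — spectra are
  assumed background-corrected upstream, so only a small residual
  remains and is absorbed by the MCR components); a three-Gaussian water
  band with per-cell amplitude uniform in 0.8–1.2 × the fingerprint peak
  height; shot-like noise with intensity-proportional variance plus a
  constant readout term, scaled so the peak signal-to-noise ratio is 20
  by default. With all nuisance amplitudes zero the intensity matrix
  equals `H_true @ W_true` exactly.
- **ARA model**: a positive-weighted linear response dominated by PHB
  (weights PHB 6.0, cytochrome 0.5) plus a size-group offset and
  Gaussian noise (SD 0.4), truncated at zero, in arbitrary activity
  units (all downstream statistics — R², p-values, importance rankings —
  are unit-free). The default offsets plant a G3 − G1 difference of
  about three within-condition SDs inside a phase, the regime in which
  a four-replicate t-test detects the effect most of the time. The
  noise SD is set so held-out prediction accuracy sits in the reported
  high-R² regime; a low-noise variant (SD 0.15) represents the
  best-measured conditions. Two tables are produced: the pot-level
  table (4 replicates per phase × size condition, mirroring the assay
  design) and a per-nodule table driven by each nodule's realized mean
  composition.

What the generator does **not** emulate: cosmic-ray spikes, instrument
drift across sessions, imaging rasters, non-Gaussian band shapes,
wavenumber miscalibration, or correlated (non-linear) relations between
components and ARA. Passing tests therefore demonstrate that the
pipeline recovers the planted statistical structure under realistic
noise — not that the biological conclusions would survive artifacts the
simulator omits.

## Regression and tests

- **Observation unit.** ARA is assayed on pooled pot replicates, so the
  nodules measured by Raman have no individual ARA value. The default
  pairing is therefore *condition-level*: the mean standardized profile
  of each (phase, size) condition is paired with that condition's four
  pot-replicate ARA values (12 observations per size group). Nodule- and
  cell-level pairings are implemented as options; nodule-level (9
  observations per group, 3-point test sets) is noticeably limited by
  random-forest shrinkage at that sample size, and cell-level is limited
  by single-cell compositional noise.
- **RFR.** 75/25 split (stratified by growth phase so both halves cover
  the design), grid search over trees {100, 300}, depth {None, 3, 6},
  min samples per leaf {1, 2, 4} by 5-fold CV on the training part only,
  refit of the best model, held-out R², impurity-based importances
  normalized to sum to one (permutation importances behind a flag).
- **PCA** per size group with per-feature centering; loading signs are
  fixed so the largest-magnitude entry is positive.
- **t-test.** Welch's unequal-variance test (robust at n = 4) on
  `ara_total` between two size groups within one phase; no
  multiple-testing correction is applied to the size contrasts, matching
  the single-contrast reporting convention.

## Problem sizes and numerical tolerances

Recovery tests run at two scales: the full design (~830 cells), where
all six components are matched at cosine ≥ 0.95 and profile correlation
≥ 0.9, and a ~200-cell cohort, where recovery is reproducible but
closer to the margin — small-n MCR is the known weak point and is the
reason the default design keeps the full 27 × (29–32) layout. Oracle
equivalence checks (SVD vs Gram eigendecomposition, PCA vs covariance
eigendecomposition, Hungarian matching vs exhaustive permutation) are
asserted at 1e-10; water-band area agrees with trapezoidal integration
within 5 % at SNR 20 (the analytic area includes Gaussian tails just
outside the window, a ~3 % difference by construction). Scaling any
cell's raw spectrum by a constant leaves its standardized profile
unchanged within 1 % (the tiny L1 term breaks exact homogeneity of the
profile update).

## Known limitations

- The α = 5e-05 penalty is defined under unit-max scaling; other
  scalings change its meaning.
- Rotational ambiguity is not analyzed; with six strongly structured,
  partially overlapping components (the aromatic metabolite shares its
  1001/1445 cm⁻¹ bands with protein and lipid neighborhoods) the
  factorization relies on non-negativity and cell-to-cell contrast, and
  degrades gracefully rather than failing loudly when cohorts are small.
- The pipeline accepts one spectrum per cell; co-addition of repeated
  acquisitions is assumed done upstream.
- ARA magnitudes are arbitrary units; only unit-free statistics are
  compared.
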