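# Methods

This note documents the models, estimators and numerical choices behind
`carsflim`, what the synthetic generators do and do not emulate, and the
limitations a user should know before trusting a green test suite.

## 1. Spectral model and the per-pixel fit

### Model

The HS-CARS spectrum at a pixel, sampled on a uniform wavenumber axis
(default 240 points over 2750–3100 cm⁻¹, matching a spectral-focusing
delay sweep), is modelled as a sum of seven Gaussian lineshapes with 21
free parameters (amplitude aₖ ≥ 0, center μₖ, width σₖ per component).
Physically the seven components tile the C–H stretch window: the first
three cover lipid CH₂ vibrations (≈2760, 2830, 2860 cm⁻¹), the fourth
and fifth protein and nucleic-acid CH₃ vibrations (≈2910, 2950 cm⁻¹).
No non-resonant background or dispersive (Fano) lineshape is modelled;
spectra are assumed background-free and positive.

Each spectrum is max-normalized before fitting (the common HS-CARS
convention; area- or vector-norm would only rescale amplitudes).
Components are re-identified after fitting by sorting on μ, so
"component 3" always means the third sub-band by ascending center. A
fit whose sorted centers leave a sub-band empty is reported as-is; no
re-anchoring is done.

### Estimator

The nonlinear least-squares problem is solved with a trust-region
reflective method using the analytic Jacobian. Loose physical box
constraints (aₖ ≥ 0, μₖ within the axis range, σₖ ∈ [2, 100] cm⁻¹)
replace a fully unconstrained search: without them, a weak component at
realistic noise can wander out of the window or flatten into a
pseudo-baseline, corrupting the sorted component identities. An
`unconstrained=True` option restores plain Levenberg–Marquardt.

At 20 dB SNR the dominant failure mode of a single-start fit is
component merging: two fitted components collapse onto the strong
2860 cm⁻¹ band while a wide stray component absorbs two neighbouring
bands, biasing the sorted third center low by 1–2 cm⁻¹ on average.
The default protocol therefore uses graduated optimization:

1. multi-start search (5 starts: uniform-grid initialization at 2775,
   2825, …, 3075 cm⁻¹ with σ = 25 cm⁻¹ and amplitudes read off the
   spectrum, plus jittered-center restarts from a fixed RNG) on a copy
   of the spectrum smoothed with a 7 cm⁻¹ Gaussian kernel — small
   against the ≈20 cm⁻¹ linewidths, large enough to suppress the
   spurious minima created by noise;
2. a single polish of the winning solution on the raw spectrum, so the
   reported parameters locally minimize the raw squared residual.

With this protocol the mean error of the sorted third center on
synthetic LNP-class spectra at 20 dB is −0.3 ± 0.3 cm⁻¹ (individual
fits still scatter with SD ≈ 6 cm⁻¹; averages over ≥200 spectra are the
meaningful quantity). Convergence tolerances are ftol = xtol = 1e−8
with at most 2000 function evaluations per stage; non-convergence and
degenerate (non-positive) spectra are flagged, never raised, and
flagged pixels are dropped from feature tables with counts logged.

### Features

Each converged fit yields 29 features in a fixed order: amplitude1..7,
mu1..7, sigma1..7, AOC1..7, AOCT, where AOCₖ = aₖσₖ√2π is derived (not
fitted) and AOCT = ΣAOCₖ. This resolves the 28-vs-29 count: 4
quantities per component would be 28; the total area is the 29th.

## 2. Refinement: sub-band energies and Otsu

Band energy is the trapezoidal integral of the spectrum over a band,
with the band edges inserted as interpolated nodes so adjacent bands
tile exactly (lipid [2750, 2890] + protein [2890, 2990] equals their
union to 1e−9). The per-pixel lipid:protein ratio invalidates pixels
whose protein energy is ≤ 1e−3 of the masked maximum instead of
producing infinities. Otsu's threshold maximizes the between-class
variance on a 256-bin histogram and returns the upper edge of the best
cut bin; by default it is computed per ratio map over valid in-cell
pixels (pool across images manually to threshold per experiment).
Ratios use raw band energies, not fitted component areas — refinement
precedes fitting in the pipeline — but a fitted-area ratio
((AOC1+2+3)/(AOC4+5)) can be formed from any FeatureImage.

## 3. Pixel classification under noisy labels

Per-pixel ground truth does not exist, so every refined pixel carries
its image's treatment-group label (random classification noise). The
classifier is a scikit-learn random forest with 100 trees; all other
hyperparameters are library defaults (unlimited depth, √p features per
split, no class weighting) and are echoed into the report. Splits are
80/20, stratified by label (stratification is this package's choice to
protect small classes). Ties in binary tree votes (probability exactly
0.5) count as the treated class. The five-seed protocol (seeds 0, 8,
16, 32, 42) retrains the forest on one fixed split and reports the
across-seed accuracy spread. t-SNE embeddings use scikit-learn with
PCA initialization and a fixed random state.

## 4. FLIM compartment features

Cell and nucleus label masks are inputs (segmentation is out of scope);
cells touching the image border are dropped, a nucleus must lie inside
exactly one cell, and cytoplasm = cell ∖ nucleus. Per compartment and
channel pair the package computes:

* **Pearson r** over masked pixels.
* **Costes thresholds**: an orthogonal regression line b = g·a + o is
  fitted on standardized channels (reduced major axis, g = sign(r)·σ_b/σ_a)
  — the standardization makes thresholds exactly equivariant under
  positive affine rescaling of either channel, which raw total least
  squares is not. T_a is scanned downward from max(a) in 256 steps with
  T_b following the line; the first (highest) pair for which the pixels
  *below* both thresholds have Pearson ≤ 0 is returned, or the scan
  floor (channel minimum) if that never happens. Channels with overall
  r ≤ 0 get thresholds a full range above the maxima: anti-correlated
  channels carry no colocalization. The colocalization gate is
  inclusive (≥), so the floor case marks every pixel colocalized and
  identical channels give coefficients of exactly 1.
* **Costes coefficients**: C_a = Σ_{coloc} a / Σ_mask a (symmetrically C_b).
* **RWC**: ranks with average ties within the mask; weight
  W = (R_max − |R_a − R_b|)/R_max; RWC_a = Σ_{coloc} a·W / Σ_mask a,
  gated by the same Costes thresholds.
* **Intensity statistics** (min/max/mean/median/SD) over the mask and
  over its 4-connected boundary (min_edge, mean_edge).
* **Morphology**: area, perimeter, eccentricity, solidity via
  scikit-image region properties.

This is a deliberately smaller, fully documented feature set (~62 per
compartment), not a re-creation of a general-purpose profiler's ~320
features. Feature columns containing any NaN or with zero variance
across cells are dropped and logged.

The optional biexponential decay fitter estimates
A(β₁e^(−t/τ₁) + (1−β₁)e^(−t/τ₂)) + c by bounded least squares
(β₁ ∈ [0,1], τ > 0), tail-fit without instrument-response
deconvolution, and reports components sorted by ascending lifetime;
which component is "bound" NAD(P)H is an instrument convention left to
the caller. A mixture that collapses onto one component is flagged
degenerate (the other lifetime is unidentifiable). τ_m = β₁τ₁ + (1−β₁)τ₂
holds by construction.

## 5. Cell-level classification

Repeated stratified random splits (default 2/3 train, 1/3 validation,
500 trials) each train a fresh 100-tree forest; degenerate draws
missing a class are re-drawn and logged. Per-hour error rates pool
misclassified and total validation-cell counts over trials before
dividing; an hour with no validation cells is reported as NaN, never
as zero error. Top-k feature selection ranks once on the full table
and re-runs trials on the selected columns (select-then-split; the
other order is available by composing the functions). The majority
baseline (modal-class accuracy) is the reference: a ~2:1 cohort gives
≈66.9%.

## 6. Synthetic generators: the stated world

**Spectra.** Per-class component-center means and SDs are the published
per-group peak-position table; each simulated cell (or standalone
spectrum) draws its seven centers from Normal(μₖ, sdₖ). Amplitudes
(0.15, 0.3, 1.0, 0.8, 0.6, 0.2, 0.1) and widths (20 cm⁻¹ for all
components) are explicit stand-ins — no real-data values are published
for them — chosen so the lipid 2860 cm⁻¹ band dominates and neighbours
overlap but remain resolvable. LNP-treated classes scale lipid
amplitudes ×1.5 globally and ×3 inside droplets (disks of radius 2–4 px
inside cells), emulating elevated lipid intensities. Cells are filled
ellipses with a smooth ±20% multiplicative interior texture; background
pixels are pure noise. SNR is defined on power against the class mean
spectrum: noise_sd = rms(mean spectrum)·10^(−SNR/20); 20 dB is the
reference noise level throughout.

**FLIM scenes.** Within each cell, β₁ and τ_m derive from two smooth
latent Gaussian fields combined by Gram–Schmidt so their empirical
correlation over the cell's pixels equals the target ρ exactly before
clipping; β₁ = clip(0.6 + 0.08·z, 0, 1), τ_m = 1.2·(1 + 0.12·y) ns,
τ₁ and intensity are independent smooth fields. The perturbation scales
keep clipping rare, so realized correlations stay within a few
hundredths of target. ρ can drift linearly with post-treatment hour
(the rising β₁–τ_m coupling of vaccine-expressing cells), and an
optional `nucleus_rho` plants the coupling only outside the nucleus.
All randomness flows from one integer seed through spawned
`SeedSequence` streams.

**What the generators do not emulate** — hence what a green test does
not establish: CARS non-resonant background and phase distortion,
photon shot noise and detector characteristics, cell-shape realism and
segmentation errors, spatial correlation of spectral noise, day-to-day
instrument drift, and any biology beyond "treated classes have more
lipid signal / drifting β₁–τ_m coupling". Accuracies measured on these
scenes validate the pipeline's mechanics and statistical behaviour, not
the published headline accuracies, which were computed on undeposited
microscope data.

## 7. Open design points, resolved

* "29 parameters" vs 4×7: AOCT is the 29th, AOCₖ derived — see §1.
* Normalization: by spectrum maximum.
* AOCT is ΣAOCₖ, not the integral of the raw spectrum.
* "Relative threshold based on Otsu": per ratio map over valid in-cell
  pixels, poolable across an experiment.
* Box constraints and graduated optimization instead of a literally
  unconstrained fit — see §1 for the failure data behind the choice.
* Biexponential components are reported sorted by lifetime; "bound"
  naming is configuration.

## 8. Limitations

Per-pixel fitted parameters at 20 dB are individually noisy (center SD
≈ 6 cm⁻¹ for the dominant band); only aggregates over hundreds of
pixels are stable. The Costes scan is O(steps × pixels) per pair and
compartment, which dominates feature-table cost on large cells. The
noisy-label protocol splits pixels, not cells, so train and test pixels
can share a cell; the held-out-image evaluation path (prediction ratios
on images excluded from training) is the stricter check. t-SNE
coordinates are seed-reproducible but not comparable across runs with
different data.
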