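# Methods

## Imaging model and calibration

A hyperspectral acquisition is a cube of raw sensor counts
`I0(r, c, λ)` on a wavelength grid covering 500–1000 nm. The default grid
samples this range at 5 nm (101 bands), chosen so that the decision bands
(540, 960 nm) and both TWI windows (955–980, 880–900 nm) land exactly on
grid points; any strictly increasing grid read from an ENVI wavelength
list is accepted. Calibration is the standard two-point model against a
white reference `Iwhite` and a dark pattern `Idark`:

    IR = (I0 − Idark) / (Iwhite − Idark),    A = −log10(IR).

Reflectance is floored at ε = 1e-6 before the log, bounding absorbance at
6 and keeping dark or occluded pixels finite instead of propagating
infinities; a white reference that does not exceed the dark pattern at a
used band is a hard calibration error, not a warning.

## Spectral parameters

* **A540, A960** — the absorbance of the single band nearest the requested
  wavelength (exact ties broken toward the lower band). A window average
  would also be defensible; the single-band reading is the simplest
  interpretation of "absorbance at 540 nm" and is what the round-trip
  identities in the test suite pin down.
* **TWI** — `100 · (mean A(955–980) / mean A(880–900) − s1) / (s2 − s1)`,
  clipped to [0, 100]. Window means are unweighted over all bands with
  centers inside the closed interval (6 and 5 bands on the default grid).
  The ratio is computed on **absorbance**, so the index increases with
  water absorption. The scaling constants default to `s1 = 0.4,
  s2 = 1.6`; vendor values are not public, and both are configurable. The
  phantom generator expresses its TWI targets on the 0–100 scale and maps
  them through the *active* (s1, s2), so cohort-level results are
  insensitive to this choice. Pixels whose denominator window mean falls
  below 1e-9 get TWI 0 and a degeneracy flag; ROI statistics exclude
  flagged pixels and report their count separately.

## ROI analysis

Regions are integer labels on the cube's spatial grid (0 = background),
annotated with ICRS grades. Grade < 2 is the healthy control class,
grade ≥ 3 the damaged class; grade 2 is rejected loudly because the
two-class design has no place for it, and silent reassignment would be
worse than an error. The per-region statistic is the arithmetic pixel mean
(median available via the `statistic` argument). For paired analysis,
multiple regions of one class within a patient are averaged first, giving
one value per patient per class; patients missing a class stay in the
table but drop out of the pairing.

## Statistics

Per index, the Shapiro–Wilk test is applied to the per-patient differences
(damaged − healthy). If its p ≥ 0.05 the paired Student t test is used,
otherwise the Wilcoxon signed-rank test (zero differences dropped —
Wilcoxon's original rule — mid-rank ties, two-sided). ROC tables are
computed only for indices whose paired test reaches p < 0.05, mirroring
the screening design; no multiplicity correction is applied across the
three indices, matching the original analysis.

ROC construction: positive class = damaged, decision rule
`score > t` (strict; a score equal to the threshold is negative),
thresholds swept over every unique score with ±∞ sentinels, so the curve
runs from (1, 1) to (0, 0). The AUC is the trapezoid area, which equals
the tie-corrected Mann–Whitney statistic U/(n₊·n₋) with ties counted ½ —
the suite checks this identity against a brute-force pair-counting oracle
and against scikit-learn. Orientation is never auto-flipped: higher score
always predicts damaged, for every index. The clinically-acceptable
threshold search returns, among swept thresholds with sensitivity and
specificity ≥ 0.80, the one maximizing Youden's J (lowest threshold on
ties), or none. Univariable logistic regression on a single score is a
monotone transform of that score and therefore yields the same ROC; the
score-based ROC is used directly.

## Synthetic phantom generator

The generator emulates the study conditions: 21 patients, one healthy
(ICRS < 2) and one damaged (ICRS ≥ 3) marked region each (~10% of damaged
regions are drawn as grade 4, the rest grade 3), 64 × 64-pixel cubes on
the default grid, circular ROIs of radius 6 (≈113 pixels).

**Index targets.** Per patient and class, the three index targets are
drawn from class-conditional marginals:

| index | healthy | damaged |
|---|---|---|
| A540 | two-component truncated-normal mixture (below) | TN(1.18, 0.48, ≥0) |
| A960 | TN(0.47, 0.10, ≥0) | TN(0.49, 0.07, ≥0) |
| TWI (0–100 scale) | N(75, 15) | N(67, 12) |

A single normal for healthy A540 cannot simultaneously match the class
moments (0.59 ± 0.27) and the operating point — it would put only ~71% of
healthy values below the 0.74 threshold against a reported specificity of
0.81. The healthy marginal is therefore a two-component zero-truncated
normal mixture — a majority low-absorbance component and a minority
high-absorbance component (physically plausible as synovium-tinged or
vascularized margins graded 0/1) — solved once against the three
constraints {mean 0.59, SD 0.27, P(≤0.74) = 0.81}:

    0.807 · TN(0.475, 0.110) + 0.193 · TN(1.072, 0.200)   (lower bound 0)

The solve (4 free parameters, 3 constraints, low-component SD fixed at
0.11) is done by `calibrate_generator` with exact truncated-normal
moments; `scripts/calibrate_defaults.py` regenerates and Monte-Carlo
verifies the frozen values. The system is underdetermined by one degree of
freedom, so equally valid nearby roots exist; the frozen root is checked
by its constraint residuals, not its raw parameters. The damaged A540
marginal needs no mixture: TN(1.18, 0.48, ≥0) already gives
P(>0.74) ≈ 0.826.

**Within-patient correlation.** Healthy and damaged draws of each index
share a per-patient latent effect through a Gaussian copula with
correlation ρ = 0.3 (a default, not an estimate — the within-patient
correlation is unknown). Draws go through each marginal's quantile
function (numeric inversion for the mixture), so marginals are preserved
exactly and rejection retries are never needed; sampled targets are
validated positive afterwards as a guard. TWI targets are converted to
window-ratio targets via the inverse TWI scaling before spectrum
construction.

**Spectra.** Each region's absorbance spectrum is the minimal smooth
family that can hit the three targets exactly:

    A(λ) = b0 + b1·(λ−500)/500 + aHb·[G(λ; 542, 15) + 0.7·G(λ; 576, 12)]
           + aW·G(λ; 968, 25)

with unit-height Gaussians (nm), a fixed small baseline slope b1 = 0.05,
and (b0, aHb, aW) solved from a 3×3 linear system whose rows evaluate the
targets exactly as the extraction pipeline does — hence the 1e-9
round-trip identity. The hemoglobin doublet at 542/576 nm encodes the
oxyhemoglobin Q-bands that physically explain the elevated 540 nm
absorbance over thinned cartilage; the 968 nm Gaussian carries the water
band. Targets whose solution dips below zero anywhere on the grid raise an
infeasibility error naming the offending wavelength. This family is a
modeling choice: any non-negative family satisfying the three constraints
would serve, this one is linear and invertible.

**Scene synthesis.** The calibration model is run in reverse:
`IR = 10^(−A)`, `I0 = Idark + IR·(Iwhite − Idark)` with a flat white
reference at 10 000 counts and a dark pattern at 50 counts, then
multiplicative sensor noise (CV 1%) on I0 and additive dark noise
(SD 1 count). The small dark pedestal (0.5% of white) keeps the
absorbance noise of even high-A540 regions (IR ~ 10⁻²·⁵) well below the
0.01 ROI-mean agreement budget between the full-cube and ROI-only paths.
Background pixels carry the healthy-class mean spectrum; they are never
analyzed. References are noise-free. Everything is driven by one
`numpy.random.default_rng(seed)` stream in fixed order, so equal seeds
give bit-identical cohorts.

**Fast path.** For replicate experiments the region table is emitted
directly from the sampled targets (with the TWI [0, 100] clip applied),
skipping cube realization; this equals the noise-free full path by
construction and agrees with the noisy full path to ≲0.002 absorbance
units per region mean. 500 cohorts run in ~15 s on one CPU; the full-cube
path is used in end-to-end tests (5 cohorts in a few seconds).

**What the phantom does not model** — and what passing tests therefore do
not show about clinical data: optical light transport (no Monte-Carlo
photon simulation), spatial texture or gradients within a region (region
pixels share one spectrum), camera PSF/blur, specular reflections,
inter-index correlation within a class beyond the shared patient effect,
and any systematic difference between surgeon-marked ROI placement and
true defect boundaries. Recovery of the cohort statistics demonstrates
that the *pipeline* is correct and well-calibrated, not that the
underlying tissue model is.

## Numerical choices

* Reflectance floor ε = 1e-6 (absorbance cap 6); TWI denominator floor
  1e-9 with flagging instead of failure.
* Nearest-band lookup breaks exact ties toward the lower wavelength.
* Mixture quantiles by interpolation on an 8192-point CDF grid spanning
  ±10 SD (error ≪ the smallest tolerance used anywhere).
* ROC thresholds include ±∞ sentinels; `argmax` tie-breaks in the Youden
  search select the lowest qualifying threshold.
* Zero-variance marginals are honored as point masses (degenerate
  configs reproduce class means exactly and separate perfectly at the
  0.74 threshold).
* Replicate experiments use seeds `base_seed + k`, k = 0…n−1; the
  acceptance run uses 500 replicates of 21 patients, sized so that
  across-replicate standard errors are an order of magnitude below the
  acceptance tolerances.

## Known limitations

* The (s1, s2) TWI scaling and the spectrum family are conventions, not
  vendor ground truth; both are explicit and configurable.
* ENVI support covers float32/uint16 payloads and bip/bil/bsq interleaves
  only — enough for this pipeline's round trips, not a general reader.
* The ROC analysis is patient-level (n = 21 per class); pixel-pooled
  variants are intentionally not implemented.
* No AUC confidence intervals, cross-validation or multivariable models.
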