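# Methods

## Box-counting fractal dimension

A binary tumor mask is a boolean lattice `(z, y, x)` with voxel spacing
carried as metadata. The FD estimate covers the lattice with a regular grid
of cubic boxes of edge `s` voxels anchored at the array origin (a box spans
the half-open range `[i*s, (i+1)*s)` per axis), counts occupied boxes
`N(s)` over a ladder of scales, and reports the OLS slope of
`log N(s)` on `log(1/s)`. Regressing on the inverse size fixes the sign so
that FD ≥ 0 for any non-empty mask; for an exactly self-similar object on
its natural ladder the points are collinear and the slope equals the
analytic dimension (filled cube → 3; level-k Menger sponge on `1, 3, …,
3^k` → `log 20 / log 3 ≈ 2.7268`).

Defaults and the reasoning behind them:

- **Size ladder**: powers of two from 1 up to a configurable maximum
  (default: the largest lattice dimension). The ladder is a pure function
  of configuration, not of each mask, so a fixed `max_box_size` gives every
  case in a cohort the identical range of scales. Powers of two also nest,
  which guarantees `N(s)` is non-increasing in `s`.
- **Grid anchoring**: a single grid at the array origin. Minimizing counts
  over all grid phases is available (`minimize_over_offsets`) for
  sensitivity analysis but is exponential in box size and off by default.
- **Fit range**: sizes up to half the largest extent of the occupied
  bounding box. Beyond that the curve flattens (a handful of boxes covers
  everything) and would bias the slope down; if the rule leaves fewer than
  two scales the fit falls back to the whole ladder and flags
  `EMPTY_FIT_RANGE`.
- **Voxel units**: counting ignores physical spacing (the classical
  algorithm operates on the lattice); spacing anisotropy with max/min ratio
  above 1.2 triggers a warning because lattice-unit boxes then mix physical
  scales.
- **QC**: every fit records `r²`; `POOR_LINEARITY` below 0.98 (configurable),
  `TOO_FEW_SCALES` below 3 fit points, and `FD_EXCEEDS_EMBEDDING` when the
  slope exceeds the embedding dimension. Exact box counts fitted on
  collinear ladders cannot exceed the embedding dimension, so the last flag
  marks either a noisy fit range or an inconsistent external estimate.
  Reference summaries of FD 3D in the motivating clinical population
  (medians 3.25/3.52) lie above the topological bound 3 for binary box
  counting; the variant or fit range that produced them is not recoverable,
  so this implementation flags such magnitudes rather than reproducing
  them. All directional analyses in this package depend only on FD
  *differences*, which are insensitive to that choice.
- **2D FD** uses the same machinery with square boxes on a chosen slice
  (default: maximum-area axial slice). No parity with any particular
  legacy 2D tool is claimed.

## Synthetic phantoms

`make_tumor_phantom(size, fragmentation, seed)` emulates the geometry the
clinical hypothesis is about: STAS-positive tumors grow discontinuously,
with small detached cell clusters around the main mass. The main blob is a
randomly surface-perturbed ellipsoid (smooth Gaussian random field added to
the normalized ellipsoid distance, thresholded at the exact quantile for
the target voxel count). A `fragmentation` fraction of the target volume is
moved into detached satellite clusters (6-connectivity detachment — the
strictest standard notion, making component counts unambiguous) placed in a
halo 1.2–1.7 normalized radii from the center; cluster sizes are drawn
log-uniformly between 1% and 5% of the main-blob volume, and at least three
satellites exist whenever fragmentation is positive. Total volume is
conserved exactly across fragmentation levels, so FD comparisons isolate
spatial continuity from size. Phantoms are deterministic per seed.

What the phantoms do *not* emulate: CT intensity, scanner noise,
reconstruction kernels, partial-volume boundaries, or realistic satellite
size distributions. Passing the FD-direction test therefore shows that the
estimator responds to spatial fragmentation as hypothesized — not that the
patient-level FD distributions are reproduced.

## Cohort simulator

`simulate_cohort` draws a binary STAS label at a configurable prevalence
(default 48/110 ≈ 0.436) and then features conditionally on the label:

- binary CT signs with the group frequencies of the reference population
  (e.g. morphological irregularity 13/48 vs 4/62);
- age and FD 2D as group-conditional normals (60.60 ± 9.18 / ± 7.52 and
  1.36 ± 0.08 / ± 0.10);
- CTR as a scaled Beta on the 0–100 percent scale, shapes fitted by
  quantile matching to the reference medians/IQRs (50.30 (19.43, 80.62)
  positive, 16.96 (2.57, 40.28) negative);
- FD 3D as a logistic location family matching the reference medians/IQRs
  (3.25 (3.11, 3.32) vs 3.52 (3.43, 3.70)).

The Beta and logistic families are stand-ins — only medians and IQRs of the
real features are known, not their distribution shapes. Because features
are drawn independently given the label, each binary feature's coefficient
in the joint logistic model of label on features equals its cross-product
log odds ratio; the parameter-recovery test exploits exactly this identity.
Real CT features are correlated (e.g. CTR with pleural indentation), so the
simulator understates multicollinearity; the VIF machinery is exercised on
the simulated designs but its values are not clinically meaningful.

## Statistical conventions

- **χ² correction policy**: uncorrected Pearson χ² by default; Yates
  continuity correction when any expected cell is below 8. This bound
  reproduces the mixed usage in the reference tables (morphological
  irregularity, min expected 7.42, matches the corrected statistic 7.306;
  smoking, min expected 9.16, matches the uncorrected 0.807); any bound in
  (7.43, 9.16] behaves identically there. The correction flag is always
  explicit in output, and both variants are directly callable.
- **Odds ratios**: cross-product with the Woolf log-interval, `z = 1.96`
  (which reproduces the printed bounds such as 1.628–17.820), and the
  Haldane–Anscombe +0.5 on all cells if and only if some cell is zero.
- **t test**: pooled variance by default (Welch behind a flag);
  **Mann–Whitney** is reported as a tie-corrected normal-approximation Z.
  The Z sign convention (positive when the first group tends larger) is an
  internal choice; only |Z| is comparable across software.
- **Logistic regression**: Newton/IRLS maximum likelihood (statsmodels),
  tolerance 1e-8, max 100 iterations; separation is reported as an error
  rather than returned as a diverged fit (detected via solver failure,
  non-convergence, or |β| > 50).
- **ICC**: two-way random-effects, absolute-agreement, single-measure
  ICC(2,1) from the mean-squares decomposition; the consistency form
  ICC(3,1) is available via `form="consistency"`. The agreement form is the
  stricter and the natural choice for test–retest of a measurement.
- **Missing values** are a hard validation error: incomplete cases are
  expected to be excluded upstream.
- Location is coded upper/middle lobe = 1 vs lower = 0 and the tumor–lung
  interface blurry = 1 vs clear = 0; these directions reproduce the
  reference odds ratios 0.659 and 0.535.

## Nomogram and evaluation

- **Points mapping**: predictor i at value v scores
  `100 · βᵢ · (v − refᵢ) / max_j |βⱼ|·rangeⱼ` points, where refᵢ is the end
  of the predictor's range minimizing its contribution (low end for
  positive β, high end for negative). Points are therefore non-negative,
  the largest-effect predictor spans exactly 100, and total points map to
  probability through the fitted linear predictor — identically equal to
  the direct inverse-logit prediction.
- **Reference equation**: the fixed linear score
  `−2.1 + 0.3·CTR + 0.2·morph + 0.15·lobulation + 0.4·FD3D` is shipped
  verbatim. Its positive FD 3D weight contradicts both the fitted
  multivariate odds ratio (< 1) and the lower FD 3D in STAS-positive
  tumors, and lobulation's multivariate direction flips its univariate one;
  the equation is provided as-is for reproducibility and no reconciliation
  is attempted.
- **ROC**: empirical curve over all distinct thresholds with rule
  `p ≥ t`; trapezoid AUC (exactly the Mann–Whitney concordance estimator);
  Youden cutoff with ties broken toward the lowest qualifying cutoff
  (favors sensitivity, deterministic); AUC CI by percentile bootstrap,
  2 000 resamples by default, seeded.
- **Hosmer–Lemeshow**: deciles of predicted risk with tied probabilities
  never split across bins; statistic `Σ (O−E)²/(E(1−p̄))` on `g − 2` df;
  degenerate bins (expected 0 or all) merged with a warning. The null
  simulation in the test suite fits the model before testing, which is the
  regime the `g − 2` reference distribution describes.
- **Bootstrap calibration**: resamples are re-binned and interpolated onto
  the apparent curve's predicted-risk grid; the report carries the
  pointwise mean and 2.5/97.5 percentile band (1 000 resamples by default).
- **DCA**: `NB(t) = TP/n − FP/n · t/(1−t)` on the grid 0.01–0.99 step 0.01,
  against treat-all and treat-none; the "useful range" is where the model
  beats both.
- **Stratification**: high risk means `p ≥ cutoff`; the group comparison
  uses the Yates-corrected χ² by default (the uncorrected value is also
  exposed); report percentages are rounded half-up to two decimals.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic inputs:
phantoms up to 64³ (tumor phantoms 48³, 20 seeds per fragmentation level),
simulated cohorts of 110–20 000 patients, 500 null replicates for the
Hosmer–Lemeshow type-I error, and 200 replicates of n = 500 for Wald
coverage. These sizes give Monte-Carlo error comfortably inside the asserted
bounds while keeping a full run in the tens of seconds on one CPU.

## Known limitations

- Patient-level headline metrics of the motivating study (AUC 0.894,
  sensitivity/specificity, Hosmer–Lemeshow p = 0.322, the multivariate odds
  ratios) require the original cohort, which is not deposited; they are
  deliberately not asserted anywhere. The simulated-cohort AUC is expected
  to land in the same vicinity but is a property of the simulator, not a
  validation.
- One reference row (vascular convergence) is internally inconsistent: the
  printed OR 2.862 and χ² 6.808 do not follow from the printed counts
  (which give 2.671 and 6.094); the package computes from counts and makes
  no attempt to match those two printed values.
- Box counting here is binary; gray-scale/differential box counting,
  lacunarity, and mesh-based fractal measures are out of scope.
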