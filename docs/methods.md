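# Methods

This note records the models, parameter choices and numerical
conventions behind `histoadi`, and what the synthetic-data world does
and does not establish.

## Tiling and background removal

A slide with declared resolution `mpp` (microns per pixel) is resampled
by the factor `mpp / target_mpp` (default target 0.5 mpp) with bilinear
interpolation; no interpolation scheme is canonical for this step, and
bilinear is the least surprising choice for downsampling H&E at these
factors. The rescaled image is covered by the largest grid of
non-overlapping `tile_px` = 224 squares fully inside it; partial edge
tiles are dropped rather than padded. Grid coordinates are 0-based,
row-major, half-open pixel intervals in the rescaled frame.

A tile is background when its global-average-pooled gray value — the
unweighted mean of the three pooled channel means — is **strictly**
greater than 200 (a tile at exactly 200.0 is kept). The filter runs
after rescaling. Two consequences worth knowing:

* the rule is monotone in brightness: brightening every pixel can only
  move a tile toward removal;
* `kept + removed = total` holds for every slide, by construction, and
  is asserted in the tests.

Intensity normalization `(x/255 − mean)/std` per channel is available
for classifiers that want it; statistics default to ones computed from
the synthetic training tiles, and externally supplied (e.g.
ImageNet-style) statistics are accepted.

## Classification

The nine canonical classes, with fixed indices 0–8 in alphabetical
order: ADI, BACK, DEB, LYM, MUC, MUS, NORM, STR, TUM. A model is
anything that maps a 224 × 224 × 3 tile to a probability 9-vector; the
assigned label is the argmax, ties broken toward the lowest index (so a
degenerate uniform model returns ADI — the tie-break is documented
behavior, not an accident).

The shipped reference model is multinomial logistic regression (L2,
C = 10) on 13 deterministic image features: per-channel means and
standard deviations, white-pixel fraction (all channels > 230),
dark-pixel fraction and dark-blob count (8-connected components of
all-channels < 120 with area ≥ 10 px), Sobel edge density, gray-level
co-occurrence contrast at horizontal and vertical offsets, and mean
red−blue difference. The two GLCM orientations let the model tell
horizontally fibered muscle from diagonally fibered stroma. Training
holds out a stratified 20% split and stores its accuracy on the model.
This classifier is a stand-in at the interface of a transfer-learned
CNN, not a substitute for one on real tissue: its ≥ 0.90 held-out
accuracy is a property of the separable synthetic textures.

## ADI scoring

ADI = (tiles labeled ADI) / (classified tiles). The denominator is all
tiles that survived the background pre-filter, *including* any the model
itself labels BACK, which matches the documented worked example
(1,000 classified tiles → denominator 1,000); `exclude_model_background`
switches to the stricter denominator. A slide with zero classified
tiles has an undefined score and reports NaN, never 0. Multi-slide
patients pool class *counts* before taking proportions, weighting each
slide by its tile count; pooling therefore equals scoring the
concatenated prediction stream.

## Survival analysis

Written from first principles (and cross-checked in the tests against a
hand product-limit oracle, a per-time hypergeometric log-rank oracle,
and an independent Cox implementation):

* **Kaplan–Meier**: S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) over distinct
  event times; subjects censored exactly at an event time count in the
  risk set at that time.
* **Log-rank**: per event time, observed minus hypergeometric-expected
  events in one group; χ² = (ΣO−E)²/ΣV on 1 df, with the
  finite-population variance d·(n₁/n)(1−n₁/n)(n−d)/(n−1) (zero when the
  risk set is a singleton).
* **Cox**: univariate Newton–Raphson on the partial likelihood, Efron
  tie handling by default (Breslow by flag; identical to 1e-10 without
  ties), covariate centered for stability, steps clipped to ±2,
  convergence when |Δβ| < 1e-8 within 50 iterations. Monotone
  likelihood (perfect separation, |β| diverging) is flagged
  `converged=False` instead of being returned silently. CIs are Wald:
  exp(β ± 1.96·se); profile-likelihood CIs are not provided.
* **Cutpoint**: candidates are midpoints between consecutive distinct
  scores; a candidate is feasible when both groups hold ≥ minprop·n
  subjects (default minprop 0.1, the conventional default of the
  R function this mirrors). The chosen threshold maximizes the absolute
  standardized log-rank statistic |O−E|/√V; exact ties go to the lower
  threshold. The search is exhaustive and equals brute force by
  construction.
* **Median split**: high means score > median; subjects at the median
  go low.

The source workflow names both an optimal-cutpoint function and median
ADI in the same breath; both are implemented, cutpoint search is the
default, and the choice is a logged config field. Users should know
that a maximally selected cutpoint *optimistically biases* the
subsequent HR and log-rank p on the same data (visible in the README
example: estimated HR 4.5 against a simulated truth of 2.0 at n = 40);
the package reports the machinery, not a cure for selection bias.

## Enrichment

* **ssGSEA**: within a sample, genes are ordered by descending
  expression, ties broken by gene id for determinism, and given rank
  weights N…1. A set's score is Σ_i [P_in(i) − P_out(i)] where P_in is
  the cumulative rank^α weight of set genes (α = 0.25, normalized over
  the set) and P_out the cumulative count of non-set genes. Rank-based,
  hence invariant to monotone transforms of a sample's values. Optional
  matrix-level normalization divides by the global score range; it is
  off by default since nothing downstream needs absolute calibration.
* **Preranked GSEA**: classical running sum — hits advance by
  |stat|^weight (weight 1 by default), misses retreat uniformly; ES is
  the maximum deviation from zero, signed. Significance by *gene-label*
  permutation (random same-size sets), two-sided on |ES|, with the
  add-one rule p = (1+k)/(1+n_perm), so p is never 0; default 1,000
  permutations.
* **Group comparison**: per-row two-sided Welch's t by default,
  Mann-Whitney U by flag, BH adjustment across rows, stars at
  0.05/0.01/0.001. The "moderated t" style of variance shrinkage is
  deliberately not implemented; with the sample sizes this pipeline
  targets, Welch is adequate and has no tuning.

## The synthetic world

The generators state a world in which every downstream estimate has a
known truth:

* **Tiles**: parametric geometric textures (disks, rings, ellipses,
  stripes, speckle) in class-specific palettes. Every foreground class
  keeps its mean gray below the 200 threshold — stroma's palette was
  darkened during design for exactly this reason — while BACK sits near
  245, so the background filter behaves as it would on tissue. The
  textures are built for separability, not realism: no stain physics,
  scanner artifacts, pyramid levels, or inter-lab stain variation. A
  green classifier test says the *pipeline plumbing* is correct, not
  that the reference features would classify real H&E.
* **Slides**: interior tile labels apportioned exactly by the
  largest-remainder rule (floor quotas, leftovers to the largest
  fractional remainders, ties by canonical class order), placed
  uniformly at random; an optional pure-BACK border emulates empty
  glass. Ground-truth label grids ride along in the PNG's JSON sidecar.
* **Cohorts**: ADI ~ Beta(2, 5) (right-skewed scores, median ≈ 0.26,
  plausible for adipose fractions); survival exponential with hazard
  0.1 per unit time stepping by exp(log HR) above the true cutpoint
  0.25; independent exponential censoring at rate 0.02. The step-hazard
  form matches the dichotomized analysis downstream; a continuous
  effect is available but off by default.
* **Expression**: gene-level Normal(0, 1) noise with a constant mean
  shift added to designated set members in high-ADI samples.

All generators draw from a private RNG stream seeded from the spec seed
(tile sub-seeds derived from seed and grid index), so identical specs
give bit-identical data.

## Numerical conventions and degenerate inputs

Probability vectors must sum to 1 within 1e-6; expression ties break by
gene id; a gene set overlapping the universe in fewer than 2 genes is
skipped with a warning; a constant comparison row gets p = 1 with a
warning; constant correlation input reports NaN; zero-tile slides
report NaN scores. Config validation rejects unknown keys and
out-of-range values (threshold ∉ [0,255], minprop ∉ (0,0.5), …) naming
the offending field.

## Known limitations

Univariate survival models only (no multivariable adjustment, competing
risks or PH diagnostics); no stain normalization beyond channel
statistics; no spatial statistics on label maps; immune-infiltration
deconvolution tools are external and out of scope — only the group
comparison applied to such scores is provided; the reference classifier
is not transferable to real slides.
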