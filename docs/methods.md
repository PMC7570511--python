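# Methods

This note documents the models, numerical choices and limitations behind
`mrbvi`. It is written for users who want to know *why* the package
computes what it computes, and what its synthetic validation does and does
not demonstrate about real imagery.

## Chromatic normalization and the index set

All indices operate on chromatic coordinates, each band divided by the
band sum. This removes per-pixel brightness exactly: scaling a pixel's
digital numbers by any c > 0 leaves (R, G, B) unchanged, which makes the
indices robust to illumination differences between acquisition dates —
the property that makes uncalibrated RGB time series usable at all.
Pixels with zero band sum carry no color information and are masked
invalid rather than filled.

The eight indices are ExR (1.4R−G), NGBDI ((G−B)/(G+B)), COM1
(G/(R^k·B^(1−k)), k = 0.667 by default and configurable), ExB (1.4B−G),
WI ((G−B)/(R−G)), IKAW ((R−B)/(R+B)), CIVE
(0.441R−0.811G+0.385B+18.787) and MRBVI ((R²−B²)/(R²+B²)). Two
numerical decisions deserve mention:

- **CIVE on normalized bands.** CIVE was historically defined on 0–255
  inputs; here it is applied to the normalized [0,1] bands like every
  other index, because the pipeline normalizes first and makes no
  exception. The additive constant then dominates the value but not its
  ordering across plots, which is all the regressions use.
- **WI singularities.** WI is unbounded as R → G. Pixels with
  |R−G| < 1e-9 are masked invalid rather than clipped, so a handful of
  near-singular pixels cannot dominate a plot mean. Masking (not
  clipping) was chosen because a clipped value would still be arbitrary;
  the remaining near-singular-but-unmasked pixels are why WI is the most
  volatile index in practice and in the test suite.

## Canopy segmentation

A pixel is canopy iff ExG − ExR > 0, equivalently 3G − 2.4R − B > 0.
Zero is the natural sign boundary of the criterion and the standard
published choice; no Otsu step and no morphological cleanup are applied,
because downstream statistics are means over thousands of pixels and are
insensitive to isolated misclassifications. The threshold is exposed for
sensitivity analysis.

## Plot-level evaluation

Per plot and date, each index is averaged over pixels that are both green
and valid inside the plot ROI; plots with zero green pixels (possible
early season) yield an undefined observation that is dropped from that
date's regression rather than imputed — early stages are genuinely
background-contaminated and imputing them would fabricate signal. R² is
the squared Pearson correlation of the simple OLS fit, reported per date
and averaged across dates per index.

Error metrics are RMSE, MAE, and AE — the *sum* of per-sample relative
errors Σ|Pᵢ−Mᵢ|/Mᵢ. Because the summed form grows with series length,
the per-sample mean (AE/n) is reported alongside it.

For trajectory comparison, each index's per-date spatial average and the
SPAD series are min–max normalized and compared with MAE/AE. Two edge
cases are handled explicitly:

- **Orientation.** Several red-driven indices *fall* as chlorophyll
  rises (MRBVI among them: more chlorophyll means less red relative to
  blue). An anti-correlated series carries the same trajectory
  information with opposite sign, so a series whose correlation with
  SPAD is negative is compared as 1 − normalized, and the flip is
  reported in an `inverted` column.
- **AE at the series minimum.** Min–max normalization sends the SPAD
  minimum to exactly 0, where a relative error is undefined; that date
  contributes no AE term. MAE is unaffected.

## Yield models

Features are the per-plot index means over a date window (default: the
last 8 of 11 dates, the period after canopy closure when plot color
reflects physiology rather than cover fraction), ordered index-major,
date-minor. With 8 indices this is a 20 × 64 matrix — far more features
than samples, which drove the regularization choices below. All
hyperparameters are exposed in `YieldModelSpec`.

- **BP**: one hidden layer of 10 logistic units trained with L-BFGS,
  capped at 500 iterations, L2 penalty α = 1.0. The strong penalty is
  deliberate: an unregularized 64→10→1 network has ~650 parameters
  against 19 training rows.
- **SVM**: epsilon-SVR, RBF kernel, C = 10, ε = 0.1, γ = 1/n_features.
- **RF**: 500 trees, unlimited depth, no feature scaling (scale-free).
- **ELM** (implemented in this package): input weights and biases drawn
  uniformly from [−1, 1] once per seed; hidden activations
  H = sigmoid(XW^T + b); output weights solve the ridge problem
  min ‖Hβ − y‖² + λ‖β‖² via SVD, which is exact and stable down to
  λ → 0 (where the fit interpolates whenever H has full row rank). The
  default λ = 1e-2: with 20 hidden units and ~19 training rows, a
  near-zero ridge is an interpolating fit whose leave-one-out error was
  measured at up to three times the yield sd, while λ = 1e-2 is stable
  across seeds. Interpolation behaviour remains available by passing a
  smaller λ explicitly.

Leave-one-out evaluation trains on n−1 plots and predicts the held-out
plot, with *all* preprocessing — per-column mean imputation of undefined
cells and z-scoring for BP/SVM/ELM — fitted on the training fold only, so
the held-out plot can never leak into the standardization statistics. The
folds are identical across model kinds. The 15%-relative-error band count
mirrors the error lines conventionally drawn on predicted-vs-actual yield
scatterplots.

## Scale-up mapping

Before mapping, the chosen model is refit on all plots (mapping is an
application of the final model, not a validation). The per-pixel feature
vector replicates the training layout exactly and is checked by label
comparison. By default the map covers only pixels classified green on the
final window date: the model was trained on green-pixel statistics, and
applying it to soil is out-of-distribution; `mask_non_green=False` maps
everything. Predictions run in chunks of 200k pixels to bound memory.

## The synthetic season generator

The generator emulates the statistical structure the pipeline assumes,
not the optics of a real flight:

- **Geometry**: 20 plots of 80×100 px in a 5×4 grid with soil gutters,
  11 dates. At the 0.018 m ground sampling distance typical of low-
  altitude RGB mosaics, an 80×100 px plot is ≈ 1.4 × 1.8 m.
- **Canopy closure**: fraction f(t) = logistic(rate·(t − midpoint)),
  defaults midpoint 2.5 and rate 1.2 per date step, so the first three
  dates are mostly soil and the window dates are near-closed — the
  pattern that makes early-date regressions weak and late ones strong.
  Canopy pixels are a uniformly random subset of exact size round(f·n),
  making the painted fraction deterministic and the truth oracle exact;
  plant morphology is deliberately not modelled because only the
  fraction matters to the statistics downstream.
- **Chlorophyll**: per plot, chl(t) = base + amplitude·f(t), with base ~
  U(24, 28) and amplitude ~ U(14, 28) SPAD units. The narrow base spread
  and wide amplitude spread concentrate the between-plot variance in the
  late season, as nitrogen-driven differences are in real trials. SPAD
  readings add N(0, 1) measurement noise.
- **Leaf color**: a deterministic map from chlorophyll to chromaticity.
  The red/blue ratio is solved so that canopy MRBVI is an *affine,
  strictly decreasing* function of chlorophyll between two anchors
  (MRBVI 0.90 at SPAD 20, −0.70 at SPAD 55) — higher chlorophyll means
  lower red relative to blue — while the green share rises 0.43 → 0.46
  along a smoothstep. This builds the red-band chlorophyll sensitivity
  into the data by construction, which is exactly what the index
  regressions are supposed to detect; it also means the generator favors
  MRBVI in trajectory ranking by design, so that ranking validates the
  machinery, not the index's merit on real crops.
- **Rendering**: chromaticities are jittered (sd 0.01, then renormalized
  to the simplex), scaled by a per-pixel brightness ~ U(120, 240), and
  rounded to 8-bit digital numbers, so the brightness invariance of the
  normalization is genuinely exercised and quantization error is
  present.
- **Yield**: intercept 5 + 0.55 × (mean chlorophyll over the last 3
  dates) + N(0, 0.8) g per hundred grains, giving yields of ~26–36 g —
  a realistic hundred-grain weight for maize — with a signal-to-noise
  ratio that leaves the learners room to differ.

Everything is driven by one `numpy` generator seeded from the config, so
a season is bitwise reproducible.

**What passing tests show — and don't.** The synthetic data have exactly
one color axis (chlorophyll), no shadows, no specular soil, no
registration error, no mixed pixels at canopy edges and no spatial
autocorrelation beyond plot membership. Success here demonstrates that
the pipeline's bookkeeping, statistics and learners are correct and
leak-free, and that they recover a planted signal at realistic noise
levels; it does not demonstrate that any index or learner will perform
comparably on real orthomosaics.

## Problem sizes used in validation

The test suite and acceptance script run the full default season
(11 dates × 20 plots, 560×370 px mosaics), 10-seed replications for the
leave-one-out noise-floor checks and 20-seed replications for the
trajectory-ranking check, with smaller seasons for structural tests —
sizes at which the complete suite finishes in a few minutes on one CPU.

## Known limitations

- Raster I/O carries an optional affine geotransform through a JSON
  sidecar rather than embedded GeoTIFF tags; world-coordinate tooling is
  out of scope.
- ROIs are axis-aligned pixel rectangles; polygonal plots must be
  bounding-boxed upstream.
- Dates are opaque ordered labels (ISO strings sorted lexicographically);
  no calendar arithmetic, growing-degree days or uneven-interval
  weighting.
- The BP/SVM/RF learners are standard scikit-learn estimators behind the
  package's interface; no hyperparameter search is performed, by design
  (n = 20 samples cannot support one honestly).
- AE's summed form makes cross-study comparison awkward; prefer the
  reported mean relative error when series lengths differ.
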