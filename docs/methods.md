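# Methods

This note records the models, numerical choices and design decisions behind
`facebmi`, and what the synthetic data generator does and does not emulate.

## The estimation problem

The outcome is body mass index, BMI = weight / height² (kg/m²). BMI
distributions in young-adult samples are right-skewed; the package models
the *reciprocal* t = 1/BMI, which is treated as the (approximately normal)
working outcome throughout. All reported r² values are squared Pearson
correlations between observed and predicted values *on the transformed
scale* (a flag on the results objects allows back-transformed evaluation;
the default matches the training scale). A constant prediction vector has
an undefined correlation; its r² is defined as 0 and flagged with a
warning rather than treated as an error, because heavily penalized null
models legitimately collapse to the training mean.

Before any model is fitted, training values more than 3 sample SDs from
the training mean (raw BMI scale) are excluded; thresholds always come
from the training folds of the current split, never from the full sample.

## Facial metrics

All three proportions are measured after a similarity-only alignment that
places the pupils horizontally at a fixed interpupillary distance
(default 90 px, centred at the origin). Operationalizations of the verbal
definitions:

* *Most lateral facial points*: extreme-x points over the face-outline
  chain, left and right found independently. (On the shipped templates a
  brute-force scan over all landmarks gives the same answer; the outline
  restriction is the documented behaviour and is user-overridable through
  the role map.)
* *Face height*: most inferior upper-eyelid point (max y, image y grows
  downward) to most superior upper-lip point (min y).
* *Midline of the lips*: the y-coordinate of the lip-corner midpoint; the
  jaw width is measured between the outline points at that height on each
  side, linearly interpolated along outline segments since templates
  rarely place a vertex exactly at lip height.
* *Perimeter-to-area*: the face outline closed across the top by the
  pupil-to-pupil segment; area is the absolute shoelace value, and a
  self-intersecting outline triggers a warning, not an error.

Which landmark indices play which role is a `TemplateRoleMap`, shipped for
the generator's templates and serialisable to YAML for user templates.

## Shape space

Generalized Procrustes alignment: each configuration is centred and scaled
to unit centroid size, then iteratively rotated to the running consensus
by the Kabsch rotation with reflections disallowed (faces have
handedness). The consensus is renormalised to unit centroid size each
iteration; convergence is the Frobenius norm of the consensus change
(tol 1e-8, max 100 iterations); the returned consensus is the plain mean
of the aligned configurations. No tangent-space projection is applied (not
part of the emulated procedure); held-out configurations are brought into
a training alignment by an ordinary Procrustes fit onto the training
consensus.

PCA is centring-only on the flattened (x₁,y₁,…,x_p,y_p) coordinates —
covariance, not correlation, since all coordinates share units — and
retains the smallest number of leading components whose cumulative
explained-variance ratio reaches the threshold (default 0.95).

## Color space

Color calibration regresses reference patch colors on an 11-term
polynomial expansion of measured patch colors,
[1, R, G, B, R², G², B², RG, RB, GB, RGB]; the term list is configurable
since published chart-calibration methods differ in their exact
expansions. The fit is ordinary least squares per output channel and needs
at least as many (diverse) patches as terms.

Warping uses an inverse-mapped piecewise-affine transform: the target mean
shape is Delaunay-triangulated; each output pixel's triangle and
barycentric coordinates are precomputed once per target, and each face's
source pixel follows from combining those coordinates with its own
landmarks, sampled bilinearly. Output pixels outside the target hull are a
constant 0.5 gray. Inside cross-validation the warp target is the
*training-fold* mean shape (GPA consensus rescaled to the mean training
centroid size and position), keeping the color features fold-safe; color
features are the masked face-interior pixels in fixed row-major order with
channels interleaved, optionally block-averaged (downsample 1 for
full-size data, 2 in the desk-scale study and test fixtures, a
speed/fidelity trade-off).

## Models

* **OLS** for the metric models, unstandardized (scale-free result).
* **Naive elastic net**: minimises ‖y − β₀ − Xβ‖² + λ₂‖β‖₂² + λ₁‖β‖₁ by
  cyclical coordinate descent with soft-thresholding on the Gram form
  (G = XᵀX), warm-started along the λ grid; intercept unpenalized;
  features standardized from training data (penalties are
  scale-sensitive); convergence when the largest coefficient change in a
  sweep falls below 1e-9 (1e-7 inside tuning loops). "Naive" means no
  (1+λ₂) coefficient rescaling is applied after fitting. At λ₁=λ₂=0 the
  solution equals OLS; at λ₁=0 it equals the ridge closed form; large λ₁
  produces exact zeros. The λ grid spans 0–1000 per axis, default
  {0, 0.01, 0.1, 1, 10, 100, 1000} (log-spaced; only the range is
  prescribed by the emulated procedure). The inner loop is compiled with
  numba when available, with an identical pure-Python fallback.
* **RBF SVR**: ε-insensitive support-vector regression with kernel
  exp(−σ‖u−v‖²); σ is the inverse kernel width and C the constraint-
  violation cost, both tuned; ε defaults to 0.1 on the standardized
  outcome (only σ and C are tuned in the emulated procedure). Features
  and outcome are standardized inside the fit. The quadratic program is
  solved by scikit-learn/libsvm; tests check it against a small
  quadratic-programming oracle of the dual.

Hyperparameters are selected by inner repeated stratified k-fold CV
(default 10-fold, repeated 5×) on the outer training set, maximising mean
held-out r²; ties break toward the earlier grid entry (smaller
penalties). The boundary value 1000 is not selected on signal-bearing
data, confirming the search range is adequate.

## Cross-validation design

Folds are stratified on outcome deciles — the natural continuous-outcome
reading of "stratified" — by dealing rank-binned subjects round-robin
into folds after a seeded shuffle; fold sizes differ by at most one within
each stratum. The outer loop (default 10-fold, repeated 30×) holds each
fold out exactly once; every repeat derives its fold seed deterministically
from (master seed, repeat index) and from nothing model-specific, so all
models share splits and paired comparisons are meaningful. One master
seed therefore reproduces an entire experiment.

Model comparisons are t-tests on the per-repeat mean r²: pooled-variance
two-sample (df = n_a + n_b − 2) across model families, paired
(df = n_repeats − 1) for two learners on identical features and splits.
No multiple-testing correction is applied by default (matching the
emulated analysis); a Holm adjustment is available to users via
scipy/statsmodels on the exported comparison table. A caveat the test
suite makes explicit: repeat-level t-tests are calibrated with respect to
fold-split randomness (≈5 % type-I rate when the same null features are
re-split), but anti-conservative for comparing *different* feature sets
on one sample, because per-repeat means cluster around each model's
dataset-level r². This is a known property of repeated-CV t-tests and is
inherited from the emulated design.

On the combined shape+color feature set both learner families are run
(elastic net and RBF SVR) and the better one defines the combined
headline, mirroring the original comparison design. On the generator's
purely linear data the elastic net usually wins; the SVR's advantage on
real faces presumably reflects nonlinear structure the generator does not
contain.

## The synthetic generator

The generator is a statistical stand-in for an unreleased photograph
collection — there is no generative model of real faces to copy, so every
choice below is a documented invention aimed at reproducing the
*statistical structure* the analysis assumes.

* **BMI**: sampled as 1/T with T normal, truncated to BMI ∈ [12, 60],
  moment-matched (by bounded least squares on the truncated-normal
  integrals) to mean 23.24 and SD 3.61 kg/m². This law is right-skewed
  raw and exactly normal after the reciprocal transform, so Shapiro-Wilk
  rejects the raw values at n = 526 while passing 1/BMI — the behaviour
  the analysis pipeline presupposes. A log-normal would *not* work here:
  its reciprocal is log-normal again and equally non-normal. The 3-SD
  rule removes ≈5–8 high-BMI subjects per 10-fold training set at
  n = 526, all overweight, an emergent property of the skew.
  The latent adiposity score z is the standardized reciprocal-scale BMI —
  an exact standard normal, monotone in BMI.
* **Heights** N(166.02, 6.33²) cm; weights back-solved from BMI; ages
  N(21.3, 2.87²) with a ~0.4 % missingness rate.
* **Template**: a schematic face (outline, hairline, brows, eyes with
  pupils, nose, lips) built for any point count ≥ 20 by a deterministic
  part-allocation rule; 154 points by default so the full-scale geometry
  matches the emulated delineation, 20–60 points in tests for speed.
* **Shape signal**: lower-face and cheek x-coordinates scale by
  (1 + shape_effect · z · g(y)) with g growing linearly from the mid-face
  toward the chin, so the jaw widens faster than the cheeks (cheek-to-jaw
  ratio falls with BMI; fWHR rises). Default shape_effect 0.05 — a 5 %
  jaw-breadth increase per BMI SD, a plausible morphological effect.
  BMI-independent structure: global width/height factors, a jaw-specific
  factor (SD 0.04), and twelve smooth low-order deformation modes with
  1/m amplitude decay (fixed basis, per-subject coefficients), plus
  0.3 px landmark jitter and a random small similarity transform
  (rotation ≤ 5°, scale 0.95–1.05, small translation) to exercise the
  alignment. The smooth modes matter: with i.i.d. jitter alone the shape
  eigenspectrum is flat and the 95 % rule retains nearly everything.
* **Color signal**: skin tone shifts along a fixed axis (+R, −G, −B) by
  color_effect · z (default 0.06 intensity per SD), with per-channel tone
  nuisance (SD 0.04), radial shading toward the outline as a crude 3D
  cue (strength 0.25 ± nuisance), schematic lips and pupils for texture,
  per-pixel noise of SD 0.05 inside the face, and a constant background.
  A 24-patch color chart (synthetic reference colors) can optionally be
  rendered into the margin to exercise calibration end to end.
* **Effect-size calibration**: the defaults were set once so that the
  generator reproduces the qualitative structure of the emulated study —
  signal shares giving combined > color-only > shape-only > metrics in
  cross-validated r², a combined model above r² ≈ 0.5, and a color PCA
  retaining roughly twice as many 95 %-variance components as the shape
  PCA (≈110 vs ≈65 at the desk scale) — and then frozen. Passing tests on
  this generator demonstrates that the pipeline recovers known signal
  with correct fold hygiene; it says nothing about photographic
  confounds (lighting, pose, expression, makeup) or about effect sizes in
  real faces, where holistic models explain far less variance.

## Problem sizes

The desk-scale reference study (`desk_study_config`) uses 200 subjects,
a 60-point template, 64 px images with downsample 2, 3 repeats of 10-fold
outer CV, inner 5-fold CV repeated 2×, and a 6-value λ grid — the
package's choice of a configuration that exercises every stage of the
full design at interactive cost (≈45 s on one CPU). The full-scale
defaults (526 subjects, 154 points, 30 repeats, 10-fold inner CV repeated
5×, 7-value grid) are what `ExperimentSettings()` gives you out of the
box and are the configuration to use on real data.

## Known limitations

* The generator is linear in its latent score by construction; nonlinear
  adiposity cues (and hence a realistic SVR advantage) are absent.
* Reanalysis mode treats supplied PC scores as fixed features rather than
  refitting PCA inside each fold — an approximation, flagged in its
  docstring.
* The color pipeline stays in RGB; no CIELab or spectral modelling.
* Squared-Pearson r² is bounded below by ≈1/(fold size − 1) for any
  non-constant predictor, so very small folds inflate null r²; null
  checks in the tests use fold sizes ≥ 30.
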