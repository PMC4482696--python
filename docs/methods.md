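# Methods

## Model

`vegmosaic` models the distribution of K vegetation types over a raster
landscape as a multinomial logistic (softmax) regression: each pixel gets a
vector of relative probabilities, not a hard class. The model is
correlative and at equilibrium — it encodes a space-for-time substitution
in which the vegetation of sites that will be warmer is predicted from what
grows at warm sites today. It has no dynamics: no dispersal, succession,
fire, disease, or time lags, and it cannot predict novel vegetation types,
because the projection is zero-sum over the K types it was trained on.

Predictors enter through a fixed basis: each predictor is z-scored against
the *training* mean and standard deviation, then expanded into intercept,
linear, quadratic, and all pairwise interaction terms (36 columns for seven
predictors; 1 + p + p + p(p−1)/2 in general). The training scaling is
stored with the model and reused verbatim at projection time, because
future climates routinely leave the training range and the basis must
extrapolate on a consistent scale. A pixel whose z-score falls outside the
training range for a predictor is counted as non-analog and the per-layer
fraction is reported with every projection; nothing is masked.

### Fitting

Coefficients are estimated by maximum conditional likelihood. The
optimizer is L-BFGS on the negative log-likelihood with the analytic
gradient, followed by up to 30 exact Newton steps (full Hessian, cheap at
the (K−1)·M ≤ 2000 parameter sizes this package targets) that drive the
maximum absolute score below 1e-9·n. This matters because the score
equations for the intercepts *are* the column-sum constraint: with no
penalty, fitted per-class probability sums equal observed class counts, and
the Newton polish makes that hold to ~1e-10 relative rather than the ~1e-5
a quasi-Newton stop would leave.

A ridge penalty on non-intercept coefficients (default 1e-6) keeps
quasi-separated fits bounded; with it the column-sum constraint holds only
approximately, so `ridge=0` is available and used wherever the exact
constraint is asserted. With `ridge=0` an unbounded likelihood (complete or
quasi-complete separation) is detected by runaway coefficients (|β| > 30,
i.e. beyond softmax saturation) or a numerically perfect fit, and reported
as an error advising a positive ridge. Probabilities are computed with
max-subtraction and are overflow-safe for logits to ±1e3 and beyond.

The reference class is the first class in sorted label order; probabilities
are invariant to this choice. Argmax assignment breaks ties toward the
lowest class index. Model selection uses BIC = −2·logL + P·ln(n)
(P = (K−1)·M); drop-one importance refits the model from scratch on each
reduced basis and reports ΔBIC against the full model, alongside
climate-only and fixed-only fits.

### Evaluation baselines

Three closed-form baselines calibrate the headline accuracy: random
assignment in proportion to observed frequencies is correct with
probability Σfⱼ²; always choosing the most common type is correct with
probability max fⱼ; and stochastic assignment from the model's own
probabilities is correct with expected probability mean(p<sub>i,obs</sub>)
— the analytic limit of repeatedly sampling assignments. Applied to the
published SFBA area table (22 types, grassland 35.9%), the first two give
17.4% and 35.9%.

## Impact decomposition

Change at a pixel between baseline and a scenario is the Bray-Curtis
dissimilarity of its two probability vectors — for probability vectors,
exactly half the L1 distance, bounded in [0, 1], and approximately linear
along compositional gradients. Across the scenario ensemble:

- **Sensitivity** (per °C) is the through-origin least-squares slope of
  dissimilarity on local warming, slope = ΣD·ΔT / ΣΔT²; the baseline
  scenario is excluded since it contributes only the origin, which
  through-origin regression makes redundant. Residual variance per pixel is
  reported as a diagnostic.
- **Exposure** (dimensionless) is the through-origin slope of the local
  warming series on the regional mean series; < 1 means warming slower than
  the region. Through-origin is chosen for symmetry with sensitivity.
- **Vulnerability** is the exact elementwise product.

Warming is tracked by mean annual temperature (MAT) change, operationalized
on the synthetic grid as the mean of the summer-maximum (JJA) and
winter-minimum (DJF) layer changes — a deliberate proxy for a mean over
monthly minima and maxima, which the synthetic grid does not carry.

Per-type regional frequency trajectories are fitted with three candidate
forms in warming — linear, quadratic, and a·exp(b·ΔMAT) — each with an
additive linear precipitation term, compared by Gaussian BIC computed
identically for all three (k·ln n + n·ln(RSS/n)). The exponential is fitted
by nonlinear least squares seeded from a log-linear fit, because a log
transform alone mishandles additive noise near zero frequencies. Direction
is *hump* when a winning quadratic has an interior maximum inside the
warming range, *flat* when no warming term is significant at the configured
level (default 0.05, per-term), otherwise increase/decline by the fitted
trend. The per-type regressions use absolute frequencies fⱼ; proportional
changes are derived from them where needed.

Spatial correlates of sensitivity are estimated by OLS of the per-pixel
sensitivity on raw baseline predictor values, with an R² comparison after
dropping a caller-chosen subset, and partial-slope data for plotting.

## Synthetic landscape generator

The generator is first-class code: it defines the conditions under which
every downstream guarantee is tested.

- **Predictor fields.** Seven layers (JJA, DJF, PPT, CWD; soil depth, wind,
  March radiation) are built by Gaussian-smoothing white noise (default
  kernel length 6 px), standardizing, and mixing the independent fields
  through the Cholesky factor of a target correlation matrix. Default
  targets reproduce the strong observed structure of a coastal
  Mediterranean-climate region — r(PPT, CWD) = −0.7, r(JJA, CWD) = 0.62,
  r(JJA, DJF) = −0.61 — completed with r(JJA, PPT) = −0.5, without which
  those three values do not form a positive-definite correlation matrix.
  All |r| must stay below the 0.8 collinearity ceiling. A light
  (weight 0.2) blend of deterministic coast-distance and elevation
  gradients adds geographic realism; it perturbs pairwise correlations by
  at most w² ≈ 0.04, inside the ±0.1 tolerance. Fields are scaled to
  physical units with marginals typical of such a region (e.g. JJA
  26 ± 4 °C, PPT 800 ± 250 mm) and floored where physically nonnegative.
  Non-positive-definite target sets fail with the offending pairs named.
- **Truth surface.** Ground-truth coefficients are drawn iid
  N(0, 0.3²) over the full basis. The scale is calibrated so the truth's
  average per-pixel maximum probability is ≈ 0.5 — a landscape where most
  pixels are plausible for several types and some are near-certain, the
  regime real vegetation models report — rather than a saturated
  one-type-per-pixel toy. Extreme surfaces cap logits at ±50, which already
  saturates the softmax.
- **Vegetation maps** are sampled pixelwise-independently from the truth
  probabilities, so sampled frequencies converge to the truth's mean
  probabilities (TV ≲ 3/√N).
- **Scenario ensembles.** Regional warming spans 0.69–5.67 °C with
  endpoints included by construction (a linear ramp over the ensemble);
  precipitation change is uniform on −23..+38% and independent of warming.
  JJA and DJF warming split antisymmetrically around the MAT change (JJA
  15% steeper, matching the slightly faster summer warming such ensembles
  project), so their mean is exactly the nominal ΔMAT. CWD rises
  ~31 mm/°C with a weak negative precipitation response, so it increases in
  almost all scenarios, including wet-but-warm ones; ensemble correlations
  of JJA/DJF/CWD changes with ΔMAT are ≈ 0.95 by default (the `coupling`
  knob). Per-pixel change scales the regional change by (1 + a·g) for a
  smooth zero-mean pattern g with max |g| = 1 and default amplitude
  a = 0.2, giving exposure slopes in [0.8, 1.2] with area-weighted mean
  exactly 1. Fixed layers are never perturbed. The spatial covariance of
  real downscaled-GCM change fields is unknown at this resolution; the
  amplitude knob is a stand-in, not an estimate.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: predictor
cross-correlations and spatial autocorrelation, a known multinomial truth,
fixed-layer conservation, warming-coupled drivers with independent
precipitation, and smooth local/regional change ratios. It does not emulate
real geography, water-balance physics, fog, coastal inversions, or
disturbance; passing tests therefore demonstrate correctness of the
*method* under known conditions, not predictive skill on real rasters.

## Numerical and design choices

- Optimizer tolerances: L-BFGS ftol 1e-12-scale, then Newton to max
  |score| < 1e-9·n; 500 iteration cap with diagnostics on failure.
- Ties in argmax assignment: lowest class index, deterministic.
- Interaction columns ordered by lexicographic name pair; serialization is
  versioned JSON and round-trips bitwise.
- Degenerate Bray-Curtis (two all-zero vectors) returns 0 with a warning
  rather than failing a whole raster.
- Co-occurrence correlations with a zero-variance probability column are
  reported as missing (NaN) with a warning.
- Projection streams in row blocks; outputs agree across block sizes to
  floating-point roundoff (BLAS accumulation order varies with shape, so
  bitwise identity across block sizes is not promised; identity for equal
  calls is).
- Rasters persist as multi-band TIFF + JSON sidecars (band names, units,
  class tables); real values as float32, so round-trips are exact for
  integer rasters and ~1e-7 relative for reals. Probability fields are
  renormalized on read to restore exact row sums.
- Pipeline runs are deterministic given config + seeds; scenario stacks are
  regenerated from the seed rather than persisted, and every written
  artifact is digest-recorded in a run manifest.

## Problem sizes

Default test and demonstration sizes are chosen to exercise the full
machinery at desk scale: landscapes of 60×60 to 224×224 pixels (3.6e3–5e4
samples), 4–8 vegetation types, and ensembles of 16–54 scenarios. At these
sizes a full fit takes seconds and the complete pipeline under a minute on
one CPU.

## Known limitations

- Probability recovery at 5e4 training pixels with the default truth
  (average confidence ≈ 0.5, K = 8, 36-column basis) reaches a mean
  per-pixel total-variation error of ≈ 0.023 — the Cramér-Rao floor for
  these conditions, verified against the inverse Fisher information at the
  truth. Materially tighter recovery requires more training data or a more
  saturated (less realistic) truth surface.
- Maximum-probability maps over-represent common types and under-represent
  rare ones relative to probability-sum frequencies; regional analyses
  therefore use probability sums, and high-resolution hard-class maps are
  deliberately not a supported product.
- No spatial autocorrelation correction in fitting: labels are treated as
  conditionally independent given the predictors.
- The exponential type-response fit can fail on ill-posed trajectories; it
  is then simply excluded from the BIC comparison for that type.
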