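# Methods

## Scope and model

`powdermorph` quantifies the link between particle morphology and powder
bulk density. The response is loose or tapped bulk density (kg/m³); the
predictors are fraction-weighted composites of per-size-class ECDF-decile
shape features. The statistical model is deliberately the simple,
interpretable one used in powder chemometrics: single-response PLS with
cross-validated component selection, benchmarked against a small
feed-forward network.

## Shape factors

All nine factors are computed from the boundary polygon, not from pixel
counts: area by the shoelace formula, perimeter as the polygon arc length,
Feret diameters by exact calipers on the convex hull (maximum over
antipodal vertex pairs; minimum over hull-edge normal widths — both
attained there, so no angular sampling error). Circularity 4πA/P²,
solidity A/A_hull, convexity P_hull/P and elongation minFeret/maxFeret are
clamped to ≤ 1: the light contour smoothing used in segmentation can push
the measured perimeter a fraction of a percent below the hull perimeter.

Elongation is defined so that 1 means equant and small values mean
elongated; with this convention "higher circularity and elongation ⇒
higher bulk density" reads as more-regular ⇒ denser, which is the
direction the synthetic density response encodes.

## Segmentation

Global Otsu threshold (polarity configurable, default dark particles on a
bright field), connected-component labelling, exclusion of border-touching
regions, minimum area 50 px². Boundaries are sub-pixel contours of the
binary mask at the 0.5 level, smoothed by a 7-vertex circular moving
average; naive pixel-staircase perimeters would bias circularity low by
~10%. On noise-free synthetic renders the extracted factors agree with the
polygon-exact truth to ≈0.3% (area), ≈1% (perimeter) and ≤0.02 absolute
(ratio factors) for particles ≥ 30 px across; the test suite enforces
2%/3%/0.03. Touching or overlapping particles are out of scope: the
generator never places them (the physical protocol disperses particles in
oil), so watershed splitting is deliberately absent.

## ECDF features

The inverse ECDF is evaluated with the type-1 (right-continuous,
`inverted_cdf`) convention: decile k is the ⌈k·n/10⌉-th order statistic,
so every feature is an observed value and the 100% point is the maximum.
The convention is a configurable argument; no interpolation rule is
claimed to be "the" correct one. Features are monotone in the percentile
and invariant to duplicating every observation.

## Variable selection

PCA is correlation-matrix PCA: SVD of the autoscaled matrix (sd with
ddof = 1); loading columns are sign-fixed so their largest-magnitude entry
is positive. The published nine-variable set (three deciles each of
maximum Feret diameter, circularity, elongation) is shipped verbatim as
the `paper9` preset — the original choice was read off a loading plot and
cannot be re-derived from other data. For new data the package provides a
reproducible rule instead: rank variables by the Euclidean norm of their
first two loadings, pick greedily, and skip candidates correlated above a
redundancy threshold with anything already picked. The default threshold
is 0.995, not a conventional 0.95: deciles of one shape factor are
correlated well above 0.95 by construction, and the reference selection
itself retains three deciles of the same factor, so only near-duplicates
are filtered. The factor-level first stage aggregates
explained-variance-weighted loading norms per factor; without the
weighting, a low-variance noise PC2 can outrank the dominant morphology
axis.

## Mixture design

Component order is (coarse, medium, fine) with default bounds
coarse 10–30%, medium 50–70%, fine 20–40%. The design is the three pure
fractions plus the seven simplex-centroid points mapped by the
lower-bound pseudo-component transform; with the default bounds the
transformed vertices hit the upper bounds exactly. Pure points sit outside
the bounded region by design. Compositing is class-blocked concatenation
(27 = 3 × 9 variables), not a weighted sum: the per-sample variable count
forces concatenation. Fractions are stored in percent and divided by 100
at compositing, so a pure sample reproduces its class's raw features.

## PLS and cross-validation

NIPALS for a single response: w ∝ Eᵀy converges in one pass, X (not y) is
deflated per component, coefficients are β = W(PᵀW)⁻¹q folded back to raw
units. Requesting more components than the effective rank (score norm
below 1e-10 relative) is an error. At full rank the fit reproduces
ordinary least squares to 1e-8, and predictions are invariant to column
scaling because autoscaling happens inside the fit.

Cross-validation uses a seeded random partition into 5 near-equal folds
(40 samples → 5 × 8); PRESS accumulates held-out squared errors, SS is
centred on the full-sample mean, and one fixed partition is used for all
component counts (the reference protocol does not state repeated splits).
Component selection: `max_q2` (argmax, smallest on ties) or the default
`parsimonious` (smallest count with Q² ≥ max − 0.02).

## Neural network

Two layers: 10 sigmoid hidden units, linear output; inputs and response
standardized internally. Training is Levenberg–Marquardt on the training
subset: solve (JᵀJ + λI)δ = Jᵀr with the analytic Jacobian; an accepted
step (training MSE strictly decreases) divides λ by 10, a rejection
multiplies by 10 and retries. λ starts at 1e-3; overflow past 1e12 before
any accepted step is an error, afterwards it is convergence. Training MSE
is therefore monotone over accepted steps. Early stopping checks the
validation subset after every epoch and stops after 6 checks without
improvement, restoring the best-validation weights. The 70/15/15 split
rounds validation and test to the nearest integer and gives the remainder
to training (40 → 28/6/6). With ~290 parameters and 28 training samples
the network is heavily over-parameterized; λ-damping and early stopping
are what keep it usable, and its results should be read as a benchmark,
not a recommended estimator at this sample size.

## Synthetic world

The generator states one fixed world rather than exposing tuning dials:

- **Pixel scale** 1 px = 2 µm, so the sieve cutoffs 180/355 µm map to
  90/177.5 px.
- **Size classes** (mean maximum Feret, CV): fine 60 px (CV 0.22),
  medium 130 px (0.12), coarse 225 px (0.12) — centred in their sieve
  bands, with the fine class wider because sub-sieve fines vary most.
- **Shape gradient**: aspect-ratio mean 0.85/0.75/0.65 and roughness
  0.04/0.10/0.18 with 0/2/4 agglomerate lobes for fine/medium/coarse —
  fines nearly spherical, coarse agglomerates irregular.
- **Brands**: four archetypes differing by a size multiplier (±6%),
  aspect shift (±0.06) and roughness multiplier (0.75–1.25), spanning a
  rounder-denser to rougher-looser range.
- **Scenes**: 3 images per (brand, class) with 40/15/6 particles
  (fine/medium/coarse), 1024² px, non-overlapping placement with border
  margin, Gaussian intensity noise sd 0.02. Three images stand in for the
  sixty photographed per physical sample; the pooled particle counts
  (~120/45/18 per class) keep the decile estimates stable while keeping a
  full run near ten seconds.
- **Density truth**: linear in the 27 composites with equal weights
  within a factor: −0.30 (kg/m³)/px on maximum-Feret deciles, +80/+55
  (loose) and +90/+60 (tapped) per unit circularity/elongation decile;
  intercepts 264/307 kg/m³; noise sd 5 kg/m³. The weights were calibrated
  once, before any model fitting, so the default study spans ≈316–679
  kg/m³ — the band reported for instant whole milk powder — with tapped
  above loose.
- **Seeding**: scene randomness is keyed by (run seed, class index, a
  hash of the generating distribution's parameters), so identical
  archetypes reproduce identical scenes and, at zero noise, identical
  densities — randomness belongs to the stated distribution, not to the
  brand label.

What a green test does *not* establish: the generator has no optics
(defocus, halos, oil-film gradients), no touching or overlapping
particles, no out-of-plane projection effects, and its density response
is exactly linear in the features the pipeline measures — so recovery
results bound segmentation and regression machinery, not real-world
predictive accuracy.

## Known limitations

- **Coefficient identifiability.** Class features are measured once per
  (brand, class) and composites are fraction × feature, so the 40 × 27
  composite matrix has structural rank ≤ 12 (4 brands × 3 fraction
  degrees of freedom). The 27 generating coefficients are therefore
  under-identified: the projection of the true coefficient vector onto
  the identifiable row space flips several signs, concentrated in the
  coarse block, whose columns are dominated by the coarse-fraction proxy
  effect. PLS at the selected component count recovers 25 of 27 signs on
  the default study; full per-coefficient sign recovery is not attainable
  by any estimator in this design, and the corresponding acceptance test
  is expected to fail. Aggregate (per-factor) coefficient directions are
  recovered robustly.
- The published regression metrics for the physical powders are not
  reproducible without the physical image sets; the synthetic study's
  metrics characterize the pipeline, not the original powders.
- Segmentation tolerances assume particles ≥ ~15 px across; below that
  the contour smoothing materially biases perimeter-based factors.
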