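# Methods

This note documents the models the package implements, the synthetic world
its guarantees are established in, the parameters that matter, and the
numerical and design decisions a maintainer would want to know. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The question and the procedure

The package asks whether a scalar physical property — an object's
real-world size — is represented as a *single dedicated axis* of the
low-dimensional "object space" spanned by a visual encoder's responses,
and, if so, what function maps physical size onto that axis and whether
the axis matters for recognition.

The chain is: (1) group objects into K log-spaced size ranks; (2) build a
K × K representational similarity matrix (RSM) from Pearson correlations
between rank-mean channel responses; (3) score size sensitivity as the
upper-triangle Pearson correlation with an ideal observer RSM,
`1 − |i − j|/K`; (4) build a PCA object space from per-channel
L2-normalized, mean-centered responses; (5) for each retained axis,
regress out its variance and measure the dropout index
`DI_i = arctanh(R) − arctanh(r_i)`; (6) test DI against a pooled empirical
null with Bonferroni correction; (7) fit six two-parameter mapping
families (linear, x^0.33, x^0.5, x², x³, log10 x) of size onto the
identified axis's scores and select by R²; (8) re-evaluate a frozen linear
readout after removing the axis (ablation); (9) check independence from
curvature (aspect ratio) and animacy.

## The synthetic world

The generator plants known structure so that every stage has a ground
truth. Its defaults are the package's study conditions.

**Sizes.** Stratified log-uniform over (1 cm, 100 m): each of the 8
log-spaced bins receives exactly 6 draws. Log-uniform is the simplest
heavy-tailed model of everyday object sizes and makes the log10 mapping
the true compressive code. Bin edges are recorded in the run manifest.

**Images.** Each object is a deformed ellipse (families: ellipse, rounded
rectangle, convex polygon, star) with elongation drawn from U(0.40, 0.85),
rasterized at a fixed bounding-box diagonal (0.72 × image width, ±2%
jitter) in the default `fixed` retinal mode, so image coverage carries no
size information. Two image cues carry size:

- *Shape:* the long-axis **orientation** sweeps 0→90° with log size
  (jitter sd 0.07 rad). Orientation survives silhouetting, is destroyed by
  a pixel shuffle, and — being a rigid rotation — cannot move the
  aspect-ratio curvature statistic, so curvature stays decorrelated from
  size by construction rather than by sampling luck.
- *Texture:* an interior grating whose **wavelength** runs 4→12 px with
  log size, with orientation loosely aligned to the object's long axis
  (sd 0.6 rad). Its histogram is wavelength-independent, so the cue dies
  under a global pixel shuffle.

Per-stimulus gray level U(0.15, 0.40) and grating contrast U(0.08, 0.18)
are size-independent nuisances. They serve two purposes: the histogram
carries no size information, and a generic (untrained) encoder's response
variance is spread over many directions, so no single principal component
of a random filter bank aligns cleanly with the size cue — which is what
keeps the dropout null well-behaved (below).

**What the generator does not emulate:** photographic appearance, object
identity and view variation, co-occurrence/context, and natural
shape–size confounds (real big things *are* boxier). Passing tests
therefore show that the *procedures* behave as claimed under their stated
assumptions, not that any particular real network represents size.

**Planted activations.** `X = C · loadingsᵀ + E` with orthonormal random
loadings (64 channels × 10 latents). The planted column carries
`beta · g(size) + ε`, `g` standardized over the sample (an axis encodes
deviations; the baseline belongs to the mean), the other nine latents are
standard normal, and `ε`, `E` have sd `noise_sd = 0.25`. With
standardization the planted variance share is `beta²/(beta² + 9)`.

Two regimes matter. At `beta = 1` (10% share) the planted variance equals
each nuisance latent's: the covariance spectrum is degenerate and the
planted eigenvector is not identifiable from 48 samples — this regime is
useful for null calibration but not for axis recovery. The generator
default is `beta = 1.4` (~16%), the weakest setting at which the axis is a
meaningful object; the pipeline default is `beta = 2` (~31%), which
reproduces the regime reported for trained networks (reference
correspondence R ≈ 0.8–0.9) and in which the dropout test recovers the
planted axis essentially always.

**Judgments.** All n(n−1)/2 pairs judged once; object *i* beats *j* with
probability Φ((log sᵢ − log sⱼ)/`weber_noise`) — a probit model on
log-size differences, i.e. Weber-consistent discrimination; 0 gives the
deterministic limit. Win proportions use denominator n with a zero
self-term.

## Stimulus transforms

- **Silhouette:** Canny edges (σ = 1, automatic thresholds), morphological
  closing (disk 2), hole filling, largest component, one-pixel erosion to
  drop the outward-biased edge ring. Near-binary inputs short-circuit to
  direct thresholding, which makes the operation exactly idempotent on its
  own output. Interior rendered 0 on white.
- **Texture surrogate:** permutation of non-overlapping 8-px tiles —
  conserves the histogram exactly, preserves within-patch (local texture)
  statistics, destroys the global contour. An optional phase-scramble mode
  (Hermitian random phases, DC preserved) keeps the full power spectrum; a
  `synthesizer` callable lets users plug in an external texture-synthesis
  algorithm. The full parametric texture-statistics matching of the
  published synthesis literature is deliberately out of scope.
- **Shuffle:** global pixel permutation.

**Curvature.** Aspect ratio P²/(4πA). A counts mask pixels. P is the arc
length of the subpixel 0.5-level contour smoothed with a 5-point circular
moving average: raw boundary-pixel counts are orientation-biased (a
rasterized disk would score ~0.81), while the smoothed-contour estimate is
within ~2% for disks, squares, and rotated ellipses — the calibration
checks (disk → 1, square → 4/π, both within 5%) are in the test suite.

## Encoder

A stack of valid convolutions (5 × 5, zero-mean unit-norm random filters
with anisotropic smoothing at random orientations — a crude V1-like bank
spanning orientations and scales), ReLU + 2×2 mean pooling between layers,
and **pre-rectification spatial channel means** at the split layer as the
output representation. The default analysis stack is 3 layers
(12, 24, 48 channels). No training is involved; determinism per seed is a
contract. Channel means are insensitive to small object translations
(boundary effects only; tested at ≤ 4 px shifts, 5% tolerance).

The frozen readout is multinomial logistic regression (C = 1) on channel
means. It stands in for downstream classification layers in the ablation:
variance is removed from the responses and the *unchanged* readout is
re-evaluated, preserving the remove-variance / frozen-downstream logic at
desk scale.

## Statistics

**RSMs and correspondence.** Similarity between rank means is Pearson
correlation (on raw channel means, no centering); correspondence between
RSMs is Pearson over the strict upper triangle (diagonals of response RSMs
are identically 1). The judgment RSM uses `1 − |Prop_i − Prop_j|/8` as
printed in the consistency convention; since proportions live in [0, 1]
this compresses entries toward 1, and a `denom="range"` flag offers the
rescaled variant.

**Dropout significance.** The null repeats the full
build-space/remove-axis/re-correlate procedure on freshly seeded untrained
encoders viewing the same stimuli, pooling the DIs of all retained axes of
every null space; p-values are upper-tail empirical with the add-one
convention, Bonferroni-corrected by the number of retained data axes
(α/k). By default the rank labels are freshly permuted inside each null
repetition (`permute_null_ranks=True`). Rationale: the untrained-network
null embodies the premise that a generic encoder carries *no size-aligned
axis*. For natural photographs that premise holds empirically; for
synthetic stimuli whose cues are deliberately legible to random filters it
does not, and the unpermuted null is contaminated by a genuine size axis
in every null space (measured null DI 99.5% quantiles of 1.6–2.0, versus
0.6–0.9 after permutation). The flag restores the premise without changing
the encoder-based null mechanics; the unpermuted variant remains available.

A deliberate consequence of in-sample axis removal: deleting the
*estimated* axis also strips the sample noise aligned with the rank
profile, so at n = 48 the residual correspondence after removing a strong
size axis slightly *anti*-correlates with the ideal observer (≈ −0.3 to
−0.6) rather than sitting symmetrically inside a permutation band.
Abolition claims are therefore tested one-sidedly (no remaining positive
correspondence against the selection-matched permutation band).

**Power at desk scale.** With 6 stimuli per rank the rank means retain
1/6 of the nuisance-latent variance, which caps the reference
correspondence near R ≈ 0.72 at a 10% planted share and hence the
attainable DI near arctanh(0.72) ≈ 0.91 — below the Bonferroni quantile of
any pooled empirical null over 8 rank bins. The dropout test is thus
underpowered in the 10%-share regime at this sample size (the
corresponding acceptance test documents the shortfall rather than papering
over it); at the pipeline's default planted strength the same test has
essentially full power and exact specificity.

**Ablation null.** Baseline object spaces are built from untrained
encoders (final layer matched to the data's channel count); each baseline
axis direction is regressed out of the *original* responses and the frozen
readout re-evaluated; drops pool across axes and repetitions; one-sided
add-one p.

**Mapping selection.** OLS of axis score on g(size). The printed textbook
orientation (size on transformed score) is exposed via
`direction="size_on_score"` with domain clipping, but the default
regresses the score on the transformed size because the log/power
transforms are undefined for signed PC scores; for a simple regression
with an invertible transform the R² is identical. All families have two
parameters, so raw R² comparison needs no complexity penalty; ties break
toward the simpler family in canonical order. R² significance uses a
permutation test rather than an F test, consistent with the
permutation-based inference used elsewhere in the package.

**Effect sizes and MVPA.** Cohen's d = β/√(dof·var β) (= t/√dof). Group
differences use the Welch t with a two-sided permutation p (the
equal-variance assumption is not otherwise needed anywhere). Decoding uses
a linear-kernel max-margin classifier (LinearSVC, C = 1, fixed solver
seed) with leave-one-group-out cross-validation; significance permutes
labels across the pooled patterns (within-group stratification available
by constructing the permutation outside). Empirical p-values use
(b+1)/(m+1) throughout.

## Numerical choices and degenerate inputs

- Fisher z is left infinite-free: |r| = 1 raises with guidance to add
  jitter rather than returning ±inf.
- PCA axis signs are fixed (largest-|loading| channel positive); the
  reported size axis is re-oriented so its correlation with log size is
  nonnegative.
- Zero-norm channels, constant RSM triangles, single-class labels,
  under-occupied rank bins, and constant regressors all raise typed
  errors (`sizeaxis.errors`) naming the offending object.
- The fast per-axis DI path forms residual rank means directly (axis
  removal is linear and commutes with rank averaging); it is tested to
  1e-12 against the composed remove→RSM→correlate path.
- Empirical-null resolution: when α/k falls below 1/(pool+1) the result
  carries a `resolution_warning` instead of silently reporting p = min.

## Problem sizes

Default study conditions: 8 ranks × 6 stimuli, 64-px images (32 px in
encoder-in-the-loop statistical tests), 64 channels, 10 latents, 200 null
repetitions, α = 0.05. The recovery/FWE/ordering/calibration guarantees
are established over 50–500 seed replicates in the acceptance suite.
Larger stimulus sets, more ranks, deeper encoders, and the 5000/1000
repetition counts of large-scale studies are configuration changes, not
code changes.

## Known limitations

- The encoder is untrained; it reads the planted image cues because they
  are linearly legible, not because of learned object knowledge. Questions
  about *which* natural image statistics a trained network uses are out of
  reach of the synthetic world (external activations can be supplied via
  the stimuli × channels CSV adapter).
- Criterion-style guarantees hold under the generator's assumptions
  (star-convex shapes, single objects, white background, one planted
  axis). Multi-axis or nonlinearly-coded size is not modeled.
- The judgment model has no lapses, order effects, or per-participant
  biases; `weber_noise` is a single global parameter.
- fMRI-side statistics are implemented at the level of their inputs
  (contrast estimates, patterns, labels); GLM fitting, preprocessing and
  spatial geometry are out of scope by design.
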