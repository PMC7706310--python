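# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Image representation

Images are `(H, W, 3)` float arrays with intensities in [0, 1]; an 8-bit
value `v` maps to `v/255`, so a published threshold such as 30/255 reads
directly on this scale. Coordinates are 0-based `(row, col)`, row-major;
every rectangle is half-open `[r0, r1) × [c0, c1)`. Relative green intensity
is `G/(R+G+B)`, with pure-black pixels (zero denominator) mapped to 0 so they
can never be classified as vegetation. No gamma correction is applied before
thresholding.

## Double-criteria thresholding

A pixel is foreground iff `R+G+B > threshold1` **and**
`w·(R,G,B) > threshold2`. Both comparisons are strict, so ties resolve to
background — in particular `threshold2 = 0` on a contrast image excludes
exactly-zero contrast. Defaults (`w = (−1,2,−1)`, `threshold1 = 30/255`,
`threshold2 = 0.02`) delete near-black pixels and keep green ones; they suit
greenhouse images with controlled backgrounds and will need retuning for
other rigs. The contrast image is the **signed** per-channel difference
`reference − image` (an absolute-difference mode is available): signedness is
what makes the published contrast parameters (`w = (1,−2,1)`,
`threshold1 = 0.7`, `threshold2 = 0`) meaningful, since a plant standing in
front of a brighter background produces a large positive summed contrast.
Requiring both the direct and the contrast mask (their intersection) makes
the result much less sensitive to either threshold.

## Morphology and plant-region identification

Dilation and erosion are the standard Minkowski operators with zero padding
outside the frame (border pixels erode away); structuring elements must be
odd-dimensioned with at least one true entry. The default refinement applies
a 5×5 closing then a 3×3 opening, written out as
dilate(5×5) → erode(5×5) → erode(3×3) → dilate(3×3). Plant-region
identification keeps the largest connected component, 8-connected by default
(plants are thin; diagonal links matter), with ties broken toward the
component whose first pixel comes first in row-major order. Empty masks pass
through with a warning rather than an error so failed segmentations survive
batch runs as zero-trait rows.

Region-of-interest detection is deliberately generic (hardware-calibrated
detectors do not transfer between imaging systems): a column is a
calibration bar when more than `bar_min_frac` of its pixels fall below a
darkness threshold on summed intensity, the ROI is bounded by the innermost
bar on each side, and its bottom is the first row (between the bars) that
looks like pot material. A manual rectangle overrides detection; if no bar
pair is found the caller gets a detection error and should fall back to the
full frame.

## HMRF segmentation

The hidden label field follows a Potts prior — each unordered neighbor pair
with unequal labels costs `beta` — and, given its label, a pixel's relative
green intensity is Gaussian with class mean and variance. The negative log
joint (up to a constant) is the energy minimized. Fitting is EM:

1. initial labels from K-means on the intensities (centers at K equally
   spaced quantiles, so the initialization is deterministic; classes
   renumbered by increasing mean);
2. ICM label sweeps in fixed raster order, each pixel taking the label that
   minimizes its local conditional energy given current neighbors, with ties
   keeping the current label — hence total energy is non-increasing within
   every sweep;
3. posterior-weighted updates of the class means and variances, with
   posteriors proportional to `exp(−local energy)` at the current labels and
   variances floored at 1e-8;
4. stop when the relative change of all parameters drops below `tol`
   (default 1e-4) or after `max_em_iter` (default 20) outer iterations, then
   one final ICM pass so the returned labels are MAP-style under the
   returned parameters.

Defaults: K = 2, `beta = 1.0`, 4-neighborhood, `max_icm_sweeps = 5`. The
plant class is the one with the larger mean relative green. Labels are
0-based internally. ICM is a deterministic approximate MAP solver: it can
stop in a local minimum, which the tests quantify by exhaustive enumeration
on 3×3 lattices. One behavior worth knowing: very dark pixels have unstable
relative green (near-zero denominator), so scenes with large dark structures
(calibration bars) can defeat a 2-class HMRF that thresholding handles —
crop or pre-filter dark regions first, exactly as the two-threshold rule
does.

## Traits

Height and width are the inclusive row/column extents of the foreground
bounding box (a single pixel has extent 1, a convention chosen so traits are
positive whenever anything was segmented), scaled by `Ysize`/`Xsize`
millimeters per pixel; size is the pixel count times `Xsize·Ysize`. Records
pivot into a plants × union-day-grid matrix with explicit NaN for unobserved
cells; duplicate (plant, day) pairs are an error, and days are numeric
(days since first imaging).

## Functional ANOVA

Design: intercept column, then baseline-coded indicator blocks per factor
(first observed level dropped) in declaration order, then pairwise
interaction blocks as elementwise Kronecker products. Every coefficient
curve uses one shared clamped cubic B-spline basis on the union day grid,
with `floor(m/2) − 4` equally spaced interior knots by default (rank
`K = degree + 1 + n_interior`; for short series supply `n_interior`
yourself). The basis is shared across plants because observation days are a
subset of one union grid per experiment.

Each observed pair (plant i, day t) contributes the row `z_i ⊗ B(t)'`;
missing cells contribute nothing (no imputation). The penalty is
`λ · I_p ⊗ Ω` with `Ω` the matrix of integrated products of basis second
derivatives, computed exactly by per-interval Gauss–Legendre quadrature (the
integrand is piecewise polynomial of degree `2(degree−2)`, so `degree` nodes
per interval suffice). The penalty applies to every column block including
the intercept — one common λ. λ is selected on a 40-point log grid spanning
1e-6 to 1e4 by GCV, `N·RSS/(N − trH)²`, with ties going to the smaller λ and
`trH ≥ N` scored as +∞. Solves use Cholesky factorizations of
`Z'Z + λD`; a rank-deficient factor design raises an error rather than
silently pseudo-inverting. Since constants and linears are penalty-free,
`trH` always lies in `[2p, pK]` and the λ→∞ limit of every curve is its best
linear approximation.

### Covariance of the coefficient curves

`β̂ = A y` is linear in the responses, so `Cov(β̂) = A V A'` with V the
block-diagonal (over plants) error covariance on each plant's observed days.
The error covariance surface is estimated from the residual curves:

1. pairwise-complete sample covariance across plants, with day pairs jointly
   observed by fewer than 2 plants imputed from the nearest estimable lag
   (with a warning);
2. **moment de-biasing**: residuals are `(I−H)ε`, and a smoother absorbs a
   large share of temporally correlated error — correlated noise looks like
   signal to it — so the raw residual covariance can understate the error
   surface by 30% and more. For a candidate surface Σ the implied residual
   covariance of plant i is
   `Σ_i − Z_iA_iΣ_i − (Z_iA_iΣ_i)' + Z_i Cov(β̂) Z_i'`; we iterate
   `Σ ← Σ + (Ĉ − implied(Σ))` (aggregated over plants on the union grid)
   until the implied surface matches the observed pairwise covariance Ĉ.
   A simple global `N/(N−trH)` factor is *not* sufficient under dependence;
   calibration simulations in the test suite quantify the difference.
3. projection onto the positive semidefinite cone (pairwise-complete
   estimates need not be PSD).

This plug-in treats the selected λ and the estimated Σ as fixed, which costs
a little coverage (bands are built with Gaussian quantiles, not t); the
Monte-Carlo calibration below measures the net effect. The de-biasing
iteration costs O(plants · (pK)² · m̄) per step and is intended for the
moderate designs this package targets; very large factor designs (hundreds
of levels) would need a stochastic trace estimate instead.

### Bands

For a contrast L over design columns, the curve is `Σ_c L_c B(t)'β̂_c`, its
variance `(L ⊗ B(t))' Cov(β̂) (L ⊗ B(t))`, and the band
`estimate ± z_{1−α/2}·SE`, **pointwise** at each t (simultaneous bands are
out of scope; default level 0.95). `ci_contrast(fit, j1, j2)` uses 1-based
column indices and treats the intercept column as the baseline level of any
factor — its effect is identically zero, so `ci_contrast(fit, p, 1)` is the
band for the last column's effect itself and `ci_contrast(fit, 1, k)` its
negative. `significance_summary` reports the maximal grid intervals where a
band excludes zero, with sign.

## Synthetic data generators

**Scenes** (`synth_scene`) emulate a side-view pot image: bright uniform
backdrop, gray pot band, dark vertical calibration bars, and a plant (stem
plus canopy) above the pot, plus an empty-pot frame identical outside the
plant. Pixel noise is iid Gaussian truncated to [0,1]; the plant color gets
a small per-pixel jitter. The default canopy is a union of axis-aligned
rectangles, which is exactly invariant under the default 5×5-closing /
3×3-opening refinement — that is what makes exact zero-noise recovery a
meaningful test; an ellipse canopy is available for less tidy shapes. What
the scenes do **not** emulate: specular highlights, soil texture, leaf
self-occlusion, illumination gradients, camera blur. Passing the zero-noise
recovery tests therefore says the operators compose correctly, not that the
default thresholds are right for any particular greenhouse.

**Growth data** (`synth_growth`) follow the functional ANOVA model with one
plant per (genotype, block, replicate) cell on `m` equally spaced days over
days 1–44 (a typical imaging season), with smooth logistic/sinusoidal true
effect curves of roughly unit amplitude around a logistic baseline of
amplitude 10. Errors are a stationary AR(1) process on the day grid
(marginal sd σ = 0.5, lag-1 correlation ρ = 0.6 by default — temporally
dependent, as repeated measurements of one plant are), and each day is
retained independently with probability 0.8 to emulate irregular imaging; a
plant that would lose all days is redrawn with a warning. AR(1) is a
stand-in for "some zero-mean dependent process": the fitting code never
assumes it, and the generator's process family is configurable.

**Calibration** (`coverage_sim`) generates replicates, refits the model from
scratch each time (default knot rule, GCV λ), and records the fraction of
(replicate, grid day) pairs whose band contains the true contrast curve. At
the default study size (10 genotypes × 3 blocks, 200 replicates) the mean
pointwise coverage of 95% bands for the block-3 effect is 93–95% across
seeds: slightly conservative-to-short, the residual gap coming from common-λ
smoothing bias on small-amplitude effect curves and from treating λ̂ and Σ̂
as fixed.

## Known limitations

- Pointwise bands only; no simultaneous bands, bootstrap, or functional
  F-tests.
- One common smoothing parameter for all effect curves: small-amplitude
  effects are smoothed at the scale of the dominant curve, which biases them
  toward linearity.
- ICM is a local optimizer; no annealing or graph cuts.
- Multi-plant scenes and unconstrained field backgrounds are out of scope;
  the ROI detector assumes one plant between two dark bars above a pot.
- The trait set is height/width/size; no convex hull, perimeter, or color
  indices.
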