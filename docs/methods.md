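# Methods

## Scope

`shgquant` quantifies collagen quality and quantity in multiphoton microscopy
of the intervertebral-disk annulus fibrosus (AF). Second-harmonic-generation
(SHG) z-stacks yield three per-sample measures — mean intensity, texture
entropy, and Otsu percent area — and two-channel collagen-hybridizing-peptide
(CHP) fluorescence images yield a mean damage intensity. A factorial
statistics layer compares groups in the two designs such studies use: a
two-factor dietary screen (sex x diet) and a 2x2 organ-culture design
(genotype x treatment). A synthetic phantom generator with known ground
truth stands in for mouse imaging data and carries all calibration and
cohort-level validation.

## Quantification pipeline

Stage order per SHG sample:

1. **Maximum intensity z-projection** of the stack (a `single-slice` mode is
   available; for thin-section stacks the literature does not distinguish,
   and projection is the default for both geometries).
2. **Background subtraction**: a scalar estimate is subtracted and the result
   clamped at zero. Default estimate is the histogram mode — deterministic
   and robust when dark background dominates the field; percentile and
   constant variants are selectable. Subtraction happens after projection (a
   single 2-D operation).
3. **ROI extraction**: a 500 x 500 px window. In `auto` mode it is centered
   on the intensity-weighted centroid of the foreground (pixels above the
   image's Otsu threshold), a deterministic stand-in for the manual selection
   of the central anterior AF; the window is clipped to the image and, for
   small fields of view, clamped to the image size. Explicit windows are
   checked strictly against the bounds. Coordinates are row-major, 0-based,
   half-open.
4. **Mean intensity** of the background-subtracted ROI, native units. No
   per-image normalization is ever applied: cross-sample intensity
   comparison is meaningful only under constant acquisition settings, and
   the pipeline preserves that contract rather than hiding its violation.
5. **Histogram equalization** by the classical CDF mapping onto 256 output
   levels (`out(v) = round(255 * (cdf(v) - cdf_min) / (1 - cdf_min))`). A
   constant ROI is degenerate (`cdf_min = 1`): all pixels map to the top
   level and a warning is logged.
6. **Entropy**: first-order Shannon entropy (bits, 256 bins) of the
   equalized ROI is the headline complexity measure; the full set of GLCM
   features (second-order entropy, energy, inertia, inverse difference
   moment, correlation) is always computed alongside, since either entropy
   definition is defensible and reporting both costs nothing. Both
   entropies use log base 2 so they share units.
7. **Otsu threshold and percent area**: the threshold maximizes between-class
   variance with ties broken toward the smallest maximizing value; percent
   area counts pixels *strictly above* the threshold ("signal above an
   automated threshold"). The threshold is computed on the
   **background-subtracted ROI** by default. This is a deliberate design
   choice: equalization rank-flattens the foreground histogram, so a
   threshold chosen on the equalized image always lands inside the flattened
   foreground mass and pins percent area near half the foreground fraction
   (numerically: true fractions 20/35/50/65/80 % read out as roughly
   13/23/32/40/46 %). That makes equalized-image thresholding useless as a
   collagen-amount measure — though it does reproduce the strong compression
   of between-group area differences seen in practice — so it is kept only
   as a sensitivity mode (`threshold_on: equalized`).

GLCM parameters follow standard texture-analysis practice: 64 gray levels
quantized uniformly over the *container* range (not per-image min-max, so
features inherit the comparability contract), distance 1, the four standard
angles accumulated, symmetric counting. Correlation is reported as missing
when a marginal SD is zero.

CHP quantification mirrors the SHG intensity contract (background-subtracted
ROI mean of the green channel, no normalization to area or cellularity) and
re-uses the SHG ROI geometry. Results carry an acquisition-batch tag;
group comparisons refuse cross-batch CHP contrasts because acquisition
settings typically differ between experiments, making intensities relative
within an experiment only.

## Synthetic phantoms

The generator emulates the features of AF collagen imaging that drive the
pipeline's outputs; per slice the noise-free pattern is

    C(x, y) = M . A . (c0 + (1 - c0) * 0.5 * (1 + cos(2 pi nu u
              + crimp * sin(2 pi nu v) + phi_d + phi_slice)))

* **Lamellae and crimp** — stripe carrier at `nu` = 0.05 cycles/px along
  coordinates rotated by ±30° (sign alternating per z-slice, mimicking
  alternating lamellae), with a sinusoidal phase modulation (`crimp` = 1.0)
  producing the characteristic waviness.
* **Fiber baseline `c0` = 0.35** — intact fibers emit everywhere; the cosine
  models crimp contrast on top of a baseline brightness. A pure cosine
  pattern (no baseline) has an arcsine intensity density with half its mass
  near zero, which makes any threshold split the fiber population itself and
  destroys the correspondence between percent area and true coverage; the
  baseline (plus the flattening effect of the z-projection) restores the
  background/fiber separation real images have.
* **Collagen fraction `f`** — a binary mask from quantile-thresholded
  smoothed Gaussian noise (correlation length 15 px), covering exactly
  `round(f * rows * cols)` pixels.
* **Disruption `d` in [0, 1]** — two mechanisms: smooth phase noise of
  amplitude `pi * d` (correlation length 25 px) scrambling the stripe
  pattern, and ablation of exactly `round(d * n_fiber)` fiber pixels via a
  second smoothed-noise field (correlation length 8 px). Ablation removes
  SHG-emitting fibrils, so entropy and percent area fall with `d` — the
  direction the entropy metric is designed to detect.
* **Noise** — observed counts are `Poisson(gain * s * C)` plus Gaussian read
  noise (default SD 1) plus a low-frequency background surface (correlation
  length 60 px, default amplitude 2), clipped to the 16-bit container.
  `gain` = 120 expected photons per unit intensity puts the images in the
  photon-limited PMT regime.
* **CHP** — green-channel rate is `gain * damage * C` with `C` built
  *without* disruption: CHP hybridizes to unfolded collagen wherever fibrous
  tissue is present (damaged regions bind more peptide, not less), so the
  expected green mean scales linearly with `damage` alone. The blue channel
  is scattered Gaussian nuclei, cosmetic only.

Cohorts derive per-sample seeds by hashing `(master_seed, group, index)`, so
adding a group never reshuffles existing samples, and regeneration is
bitwise identical. Effects are recorded as absolute parameter overrides per
design cell (exact bookkeeping in the truth table). The two presets mirror
the study geometries: the dietary design uses 7 optical slices at 1.5 µm
(thin sections, n = 12/11 with both sexes), the organ-culture design 10
slices at 10 µm (in situ, n = 5 per cell, effects confined to the
AGE-challenged wild-type cell). Effect magnitudes (intensity scale
1.0 -> 0.72 in the dietary arm and 1.0 -> 0.35 in the challenged
organ-culture cell, disruption 0.15 -> 0.45, collagen fraction
0.50 -> 0.46, damage 1.0 -> 1.8/1.6) are several-fold the within-group
spread, chosen once as the cohort conditions under which direction and
significance recovery is demonstrated.

What the phantoms do **not** emulate: optical point-spread blurring,
forward/backward SHG physics, depth attenuation, sectioning artifacts,
biological between-animal variability beyond seed-to-seed noise, or any
spatial correlation between damage and disruption. Passing cohort tests
therefore demonstrates that the pipeline recovers known effects under a
controlled, photon-limited imaging model — not that real-tissue effect sizes
or p values would match.

## Statistics

* **Percent difference** = `100 * (mean_exp - mean_ref) / mean_ref` with the
  declared reference group (control / low-AGE / wild-type control) in the
  denominator — the conventional choice, and the one that reproduces
  standard sign conventions.
* **t test**: two-tailed independent Student (pooled variance) by default,
  Welch by flag. Zero-variance degeneracies use p = 1 (equal means) and
  p = 0 with a warning (unequal means).
* **Two-way ANOVA**: fixed effects with interaction, Type III sums of
  squares under sum-to-zero contrasts (statsmodels OLS + `anova_lm(typ=3)`),
  matching GraphPad-style behavior on unbalanced designs; verified exactly
  against R `car::Anova` on an unbalanced fixture and against the classical
  hand decomposition on balanced data.
* **Post hoc**: Bonferroni over the four planned 2x2 contrasts
  (within-genotype treatment effects, within-treatment genotype effects) —
  the comparisons such figures report — not all six pairs; the family is
  configurable. Contrast t statistics use the ANOVA residual mean square and
  degrees of freedom; adjusted p = `min(1, raw * k)`.
* **Dietary mode**: the sex x diet ANOVA gates pooling — sexes are pooled
  for the diet t test only when neither the sex main effect nor the
  interaction reaches alpha; otherwise a warning is emitted and per-sex
  contrasts are reported. NaN p values from zero residual variance count as
  no evidence of a sex effect.
* **Replicate aggregation**: studies often image multiple disk levels per
  animal; `aggregate_by` optionally averages per animal before testing.
  Default is per-disk, with no claim about which a given study used.

## Numerical choices and degenerate inputs

Rounding in equalization uses banker's rounding (`np.rint`); Otsu ties take
the smallest maximizing threshold (first argmax); "positive pixel" is
strictly greater than the threshold; a constant image is an error for Otsu
(threshold undefined — the pipeline logs a warning and reports percent area
as missing), a warned degenerate case for equalization, and entropy 0. The
12-bit-in-16-bit container heuristic (max <= 4095) is opt-in only, to avoid
silently rescaling thresholds. Physical ROI area is not reported: the pixel
size of the 500 x 500 window is not normalized away.

## Problem sizes

Full phantom geometry (600 x 600 x 7-10 slices, the real acquisition scale)
is used everywhere results are reported: ground-truth recovery uses 10 seeds
per collagen fraction and 20 per disruption level; statistical calibration
uses 1000 null replicates; cohort demonstrations use the study sample sizes
(n = 12/11 and 4 x 5). The CLI smoke tests use reduced geometry since they
check plumbing, not measurement.

## Known limitations

* The entropy headline is first-order; the second-order (GLCM) entropy is
  reported alongside but not used as the primary disruption readout.
* `auto` ROI centering is a proxy for expert anatomical selection and can
  land differently than a human would on images with bright off-center
  structures.
* Cross-sample intensity comparability is assumed, not verified; the package
  only tags batches and refuses obviously cross-batch CHP contrasts.
* The phantom's disruption parameter conflates phase disorder and fibril
  loss; real degeneration need not move both together.
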