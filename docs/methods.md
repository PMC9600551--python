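# Methods

## Scope and design

`oculens` quantifies crystalline-lens opacity from anterior-segment
cross-sections.  Patient images from clinical SS-OCT or Scheimpflug
devices are not redistributable, so the package ships a synthetic
anterior-segment phantom generator with exact ground truth; every
algorithmic claim is validated by parameter recovery on phantoms rather
than by reproducing clinical cohort values.  Proprietary device
algorithms (the Pentacam's automatic 0–5 nucleus staging, vendor percent
calibration, vendor export formats) are deliberately out of scope; the
ordinal grade in simulated cohorts is a severity-quantile surrogate and
is labelled as such.

## Phantom model

A B-scan is rendered on an `768 × 1024` grid (rows = axial depth, row 0
most anterior; columns = lateral position; 14 mm scan width, so
≈73 px/mm laterally and 64 px/mm axially, i.e. a 12 mm axial window).
The scene, in depth order: background, a flat corneal band (anterior
surface at 60 px, thickness 35 px ≈ 0.55 mm), the anterior chamber
(185 px ≈ 2.9 mm), and a lens of thickness 280 px (≈4.4 mm) and width
600 px (≈8.2 mm) bounded by two quartic surfaces.  The surfaces are
generated in apex-centered form `y(u) = apex ± (0.8·R·(u/h)² +
0.2·R·(u/h)⁴)` with sagittal rise/drop `R` of 40%/52% of the lens
thickness over the half-width `h` — genuinely 4th-order, so the quartic
fit is exercised beyond its parabolic special case — and stored as
absolute-coordinate coefficients `c₀..c₄`.  Explicit coefficient
overrides are accepted and validated (posterior strictly deeper than
anterior across the lens width).

Region intensities default to background 5, cornea 90, chamber 20,
cortex 100, nucleus 140 PIU — ordered as in real scans (clear aqueous,
scattering tissue, denser nucleus) with the nucleus ellipse occupying
14% of the lens cross-section, the average nuclear share of lens area.
A radial series holds `n_scans = 15` meridians equally spaced over
0–180° (half-turn scans cover the full circle); the geometry is
rotationally symmetric while speckle is independent per meridian and
fully determined by `(seed, meridian)`.

**Speckle.** OCT speckle is emulated as multiplicative Gaussian noise,
`I = Ī·(1 + ε)`, `ε ~ N(0, sd)` (default sd 0.1), clipped to [0, 255].
This is the simplest mean-preserving model: region means converge to the
configured intensities as area grows, which is exactly the property the
densitometry oracle tests rely on.  It does *not* reproduce the Rayleigh
amplitude statistics, spatial correlation, depth-dependent attenuation,
specular apex reflex or eyelid shadowing of real scans — passing tests
demonstrate correctness of the measurement pipeline, not robustness to
every clinical artifact.  (A `central_column_margin_px` knob exists for
excluding a specular apex column in real data; it defaults to 0 because
the phantom renders none.)

**A-scan.** The axial profile is sampled at 10 µm over the 12 mm window
on a normalized [0, 1] scale: plateaus per tissue, four Gaussian
specular peaks (σ 0.03 mm) at the cornea anterior/posterior surfaces and
the lens anterior/posterior capsules.  The lens plateau defaults to
0.102 au, the magnitude of device-normalized lens backscatter.  Additive
Gaussian noise models detector noise.

**Cohorts.** Each simulated eye draws a latent severity `s ~ N(0, 1)`;
every densitometry column is `mean + sd·(λ·s + √(1−λ²)·ε)`, so the
population correlation between two columns is the product of their
loadings `λ` — an analytic handle for parameter-recovery tests (e.g.
λ = √0.7 for both columns gives ρ = 0.7).  Defaults reproduce clinically
reported marginal scales (SS-OCT lens ≈ 44.8 ± 6.7 PIU, nucleus
≈ 39.1 ± 12.9 PIU, linear ≈ 0.102 ± 0.017 au, Scheimpflug ≈ 12 ± 3–4 %).
CDE is a linear-in-severity value (3.26 ± 1.79 %s, floored at 0)
recorded only for the ≈80% of eyes operated without the femtosecond
laser; CDVA maps severity deterministically onto the decimal Snellen
ladder; the ordinal grade bins severity into standard-normal sextiles
0–5.  Values are clipped to their physical scales, which perturbs only
>3 sd tail draws and leaves configured correlations intact to well below
sampling error.

## Segmentation pipeline choices

- **Contrast stretch** (percentiles 1–99 by default) feeds thresholding
  and edge detection only; every density is computed on original pixels,
  because rescaling intensities would bias opacity values.
- **Global threshold**: ISODATA (Ridler–Calvard).  The anterior-segment
  histogram pits a heavy dark mass (background + chamber) against
  mid-to-bright tissue; the ISODATA fixed point — equidistant from the
  two class means — always lands between the chamber and tissue modes for
  such scenes, whereas classic Otsu can place its bin boundary marginally
  below the chamber level and flood the foreground.  An absolute
  `threshold_override` is available.
- **Noise removal**: connected components below 50 px are dropped, then
  a morphological closing with a 5 px disk fills small gaps.  Both
  configurable.
- **Surface extraction**: first/last foreground row per column of the
  largest component; fewer than 5 columns is rejected (a quartic is
  underdetermined).
- **Quartic fit with outlier correction**: ordinary least squares;
  points with residual > 10 px ("substantial deviation") are excluded
  from a single refit and thereby snapped onto the refit curve.  Exactly
  one pass — iterating to convergence would be a different (IRLS-like)
  algorithm.  Replacing outliers with the *first* fit's value was
  considered and rejected: the first curve is contaminated by the
  outlier, so part of the error would leak into the refit; with
  exclusion, an exact-polynomial surface with one displaced point is
  restored to the clean fit at machine precision.
- **Chamber ROI**: Canny edges (σ 2) on the stretched image; per column
  the deepest edge clearly anterior to the lens surface is the cornea's
  posterior border, median-filtered across columns for coherence; the
  ROI is eroded axially by 3 px so boundary bleed cannot contaminate the
  background estimate.
- **Nuclear ROI**: ellipse at the lens-mask centroid, aspect ratio =
  lens half-width : central half-thickness, scaled to 14% of the lens
  area and shrunk (3% steps) only if it would cross the mask boundary.
  Whether the clinical ellipse was fixed or proportional is not
  documented anywhere; proportional sizing is the only choice consistent
  with the 14%-of-area average.
- **Background subtraction** is applied per scan before series
  averaging — algebraically identical to subtracting the averaged
  chamber mean under equal weights, and more informative per scan.
  Negative corrected values are flagged with a warning but not clamped,
  since clamping would bias series averages.
- **A-scan peaks**: Gaussian smoothing (σ 3 samples), prominence-ranked
  local maxima (min prominence 0.05), the four most prominent sorted by
  depth; the linear mean excludes the capsule peaks plus a 15-sample
  (0.15 mm ≈ 5σ) guard margin on each side, because specular interface
  reflections are not lens opacity and their tails would otherwise
  inflate the mean by ~5% of its value.

## Scheimpflug methods

Percent mapping is linear, `PIU/255 × 100`; the vendor's calibration is
undocumented, and all downstream use is correlation, which is invariant
to monotone linear maps.  The octagonal ROI is regular and flat-top,
parameterized by circumradius (mask area converges to `2(1+√2)s²` with
< 1% pixelization error at circumradius ≥ 30 px).  The 3D method applies
one fixed ellipse to every image, as the manual procedure literally
does; per-image rescaling of the ellipse would be a different estimator.
Meridian selection keeps images within ±15° of the vertical axis
(circular distance modulo 180°) and falls back to the single closest
meridian so the selection is never empty.

## Statistics

- **Normality**: one-sample KS against a normal with estimated mean/sd.
  Fitted parameters invalidate the textbook KS null, so p-values come
  from a seeded Monte-Carlo (Lilliefors) null distribution, 10⁴
  replicates by default, cached per sample size.  The statistic matches
  `statsmodels`' Lilliefors implementation exactly; p-values agree on
  the α = 0.05 decision (the null approximations differ).
- **Coefficients**: Pearson (t-distribution p, n−2 df), Spearman
  (Pearson on mid-ranks), Kendall's τ_b with tie correction
  `(C−D)/√((n₀−n₁)(n₀−n₂))` and tie-adjusted normal-approximation p.
  These standard estimators are delegated to `scipy.stats`; the test
  suite verifies τ_b against an independent O(n²) brute-force
  pair-counting oracle and Spearman against the rank-Pearson identity.
- **Method selection**: ordinal/discrete → τ_b; both normal at α → 
  Pearson; otherwise Spearman.  CDVA (Snellen steps) and the 0–5 grade
  are treated as ordinal.
- **Matrix**: pairwise deletion for missing values; CDE cells use only
  non-femtosecond eyes (the laser reduces CDE by design and would
  confound it as a severity proxy); cells with n < 3 are reported
  unavailable; significance stars at 0.05/0.01/0.001.
- **Sample size**: Fisher-z, `n = ⌈((z_{1−α/2}+z_power)/atanh ρ)² + 3⌉`,
  floored at 4.  Note this standard formula gives n = 62 for ρ = 0.4 at
  90% power and α = 0.05 two-sided; published sample-size statements
  based on unstated methods may differ and are not reverse-engineered.
- **CDE utility**: `power(%)/100 × time(s)` in %s, matching the
  clinically reported 1–10 %s magnitude.
- No multiple-testing correction is applied, matching the workflow this
  layer mirrors.

## Problem sizes and determinism

Validation runs use the full-size default phantom (768 × 1024): 20
noise-free scenes with randomized geometry/intensities for the
densitometry oracle, 50 scenes at speckle 0.1 for surface recovery
(observed RMSE ≈ 0.5 px against the 3 px acceptance bound), and 50
simulated 500-eye cohorts for correlation recovery.  All randomness
flows through `numpy.random.default_rng` seeded from explicit integers;
identical seeds give bit-identical images, profiles, cohorts and result
files.

## Known limitations

- The speckle and A-scan noise models are idealized (see above); no
  motion, shadowing, or illumination-gradient artifacts are simulated.
- The flat corneal band is a simplification; the chamber-ROI logic only
  requires a coherent posterior corneal edge, which it provides.
- The cohort generator is a single-factor latent model: it cannot
  represent cataract subtypes whose modality profiles dissociate
  (e.g. posterior subcapsular opacity with a clear nucleus).
- Percent and PIU scales are related linearly for convenience; absolute
  cross-device agreement is not meaningful, only correlation is.
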