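# Methods

## The measurement

Vitreous haze — light scattering by inflammatory cells and protein in the
vitreous body — shows up on OCT B-scans as elevated signal in the normally
dark vitreous. `octhaze` quantifies it as the **vitreous/RPE-relative
intensity (VRI)**:

    VRI = mean intensity of a vitreous patch / mean intensity of the segmented RPE

Dividing by the RPE intensity normalises away global signal-strength
changes (media opacity, tear film): scaling every pixel by a constant `c`
leaves the VRI unchanged, and the test suite asserts this invariance.

The measurement pipeline (`octhaze.measure`):

1. **Segmentation.** The image is binarised (Otsu by default) and cleaned
   with a morphological opening (disc, radius 5 px) that removes speckle
   islands smaller than retinal structure; the largest connected component
   is the retina/RPE complex. Segmentation succeeds only if the component
   spans ≥ 60 % of image columns. Because the frame background below the
   choroid can be darker than the vitreous, a plain Otsu threshold
   occasionally separates the two *dark* classes instead of dark-vs-tissue;
   when the thresholded foreground exceeds `max_foreground_fraction`
   (default 0.5 — a retina band never fills half a macular B-scan), Otsu is
   re-applied within the foreground. Both the rule and the fraction are
   configuration.
2. **RPE band.** Per column, the lowest `rpe_band_thickness` (default 6)
   tissue rows. The band-extraction rule is a reimplementation choice; no
   published parameterisation exists.
3. **Vitreous patch.** All pixels strictly above the inner retinal
   boundary minus a `patch_margin` (default 10 px), restricted to the
   central `lateral_crop_fraction` (default 0.6) of columns, minus any
   tissue. A patch below `min_patch_pixels` (default 500) fails the scan.
4. **Ratio.** Means over the two masks; a zero RPE mean is a failure, not
   an exception. `analyse_bscan` composes the stages and reports any
   stage's failure reason; it never raises on a valid image.

All thresholds are exposed on `SegmentationConfig`. Pixel values are used
as provided; an optional `inverse_gamma` exponent can undo display gamma
encoding for raw-export workflows.

## The phantom generator

`octhaze.synthetic.make_phantom` renders what the measurement needs and
nothing more: a bright retina band (default rows 200–289 of a 496 × 512
frame) with a brighter 6-px RPE slab at its outer edge and a Gaussian
foveal dip (depth 40 px, width σ = width/10), over a uniform vitreous and
a dark sub-choroidal background. Degradations:

- **Frame averaging (ART).** Additive Gaussian noise with
  sd = `base_noise_sd` / √ART, clipped to [0, 1]. The default
  `base_noise_sd` = 0.08 at ART 1 gives sd 0.008 at ART 100. A property
  test verifies the 1/√N scaling empirically within 5 %.
- **Focus offset.** A separable (gain, blur) pair per offset:
  the vitreous intensity is multiplied by `focus_gain_map[offset]`
  (defaults 1.0 / 1.8 / 3.4 / 4.0 / 4.2 for 0 / −5 / −10 / +5 / +10 D,
  chosen to reproduce the observed ordering of mean VRI across offsets —
  in-focus smallest, positive offsets largest) and the image is blurred
  with a Gaussian PSF (σ = 0 / 1 / 2 px by |offset|). These are
  calibration choices, not an optical model; no quantitative mapping from
  dioptres to vitreous gain is established.
- **Bottom positioning.** The band is translated to just above the lower
  frame edge and a linear intensity roll-off (depth 80 px, floor 0.35)
  emulates the fading at the edge of the acquisition window, dimming the
  RPE and thereby raising the measured ratio.

Ground truth travels with every scan: the three region masks plus region
means computed on the noise-free rendering, so `truth.vri` is exactly what
a perfect segmentation would measure without noise. Intensities are floats
in [0, 1] in memory and 8-bit grayscale PNG on disk; row 0 is the top
(vitreous) side.

Default region intensities (vitreous 0.041, retina 0.55, RPE 0.85,
background 0.01) put the in-focus phantom at VRI ≈ 0.048, the healthy
in-focus operating point of the measurement.

What the phantom does **not** emulate: multiplicative speckle statistics
(a config-gated multiplicative option exists in spirit only — the analysis
uses region means and sds, which additive noise exercises equally), depth
attenuation, eye motion, vitreous floaters, retinal layering, or oedema.
Passing tests therefore demonstrate correctness of the *measurement and
statistics machinery*, not clinical performance on scanner data.

## The study simulator

`enumerate_protocol(n_subjects, repetitions, sections)` expands the
10-setting protocol: five ART levels (6, 12, 25, 50, 100) in focus at
middle position, four focus offsets (±5, ±10 D) at ART 100, and one
bottom-positioned ART-100 in-focus acquisition. The two five-setting
*arms* (ART arm, focus arm) share the in-focus/ART-100 row. At the
canonical size (15, 3, 7) each arm holds 1575 theoretical measurements
and each subject contributes 30 raster scans.

`generate_study` draws the VRI for subject *i*, repetition *j*, section
*k* under setting mean μ as

    y_ijk = μ_setting + b_i + c_ij + e_ijk,

with independent zero-mean Gaussians of sd `sigma_subject` (shared by a
subject across all its scans), `sigma_scan` (one per raster scan =
setting × repetition within subject) and `sigma_section`. Defaults
(0.012, 0.007, 0.010) are the simulation ground truth for the nested
variability structure; default setting means range from 0.039–0.048
(in-focus ART arm) to 0.162–0.200 (defocused/bottom), the study
conditions the simulator emulates.

Randomness policy: every random effect is drawn from a stream seeded by
(root seed, level tag, slot key), so subsetting a design never changes the
values of the remaining slots, and identical seeds give bit-identical
tables. `inject_failures` marks slots failed independently with
per-setting probabilities (defaults: 3 % for in-focus settings, 39 % for
defocused ones, matching arm-level failure rates of roughly 3 % and 32 %).

When images are requested, each slot is rendered with the vitreous
intensity set to `target_vri × rpe_mean`, overriding the gain model so the
measured VRI tracks the simulated value monotonically while noise, blur
and positioning still follow the slot's setting.

## The statistical pipeline

**Exclusions.** A raster scan must provide ≥ 3 of its 7 sections and a
subject × setting cell ≥ 2 of its 3 repetitions; otherwise the scan or the
whole cell is discarded, with every exclusion logged. The rule is
idempotent.

**Mean effects.** `fit_mean_model` fits, per protocol arm, a linear mixed
model with the VRI (or the vitreous or RPE intensity) as response, the
setting as a categorical fixed factor, and random intercepts for subject
and raster scan nested in subject (statsmodels `MixedLM`, variance
components for scans). REML estimates are reported; the overall factor
p-value is a likelihood-ratio test of ML refits against the intercept-only
model (REML likelihoods are not comparable across fixed-effect
structures). A Wald-style alternative is available through the returned
covariance. Noise-free input puts the likelihood on the boundary, so an
exactly degenerate table short-circuits to closed-form cell means with
zero variances.

**Residual decomposition.** Three levels: each measurement about its scan
mean (*within scan*), each scan mean about its cell's repetition mean
(*intra-subject*), each subject × setting mean about the across-subject
mean for that setting (*inter-subject*). All means are over available,
post-exclusion members. Inter-subject residuals are per-setting by default
(variability is reported per setting); a `pool_settings` switch centres on
the grand mean instead. Residuals in each group sum to zero by
construction — a property test asserts it to 1e−12. Singleton groups
contribute an exact zero and are flagged.

**Variability.** If residuals are approximately normal, squared residuals
are χ²-distributed — a Gamma special case — so a Gamma GLM with log link
models mean squared residual per setting; the reported variability is the
square root of the fitted mean. With a single categorical predictor the
saturated fit reproduces per-group means exactly, so the whole pipeline is
testable against a per-group RMS oracle (asserted to 1e−8). Exact zeros
are undefined under the Gamma likelihood and are dropped with a logged
count; they arise only in degenerate synthetic input, where the fit falls
back to closed-form group means. Dispersion is estimated by the Pearson
method (it does not affect the fitted means); the overall p-value is a
scaled-deviance LRT against the intercept-only model.

**Pairwise contrasts.** All level pairs, adjusted with the Tukey
(studentized-range) method over the factor's complete pairwise family:
p = P(Q_{k,ν} ≥ |t|·√2). For mean fits the contrast is on the response
scale; for variability fits it is a difference of log mean squared
residuals (so `exp(estimate)` is a variance ratio). With two levels the
adjusted p-value reduces to the unadjusted two-sided t p-value.

**Box plots.** Quartiles by linear interpolation (type 7), whiskers at
the most extreme points within 1.5 × IQR of the box, clamped never to
retreat inside the box (Tukey's convention, matching matplotlib, which the
tests use as an independent oracle); points beyond are outliers.

## Numerical and design choices

- Thresholding: Otsu default; fixed-threshold option for raw exports.
- MixedLM convergence failures are flagged on the fit, not raised.
- Covariance diagonals are clipped at zero before taking standard errors
  (boundary fits can return slightly indefinite matrices).
- Studentized-range df capped at 1e6 for numerical stability of
  `scipy.stats.studentized_range`.
- Failure accounting counts a theoretical slot as failed whether the
  measurement failed or the scan was never obtained; percentages are
  rounded to integers.
- Simulation sizes used by the test suite: the full 15 × 10 × 3 × 7 design
  for recovery checks (50 replicates); a 10-subject × 2-repetition ×
  4-section ART arm for the 200-replicate null calibration of the overall
  LRT — the package's chosen compromise between Monte-Carlo resolution and
  runtime.

## Known limitations

- The subject-level variability estimate pools only as many independent
  subject effects as there are subjects. At 15 subjects its sampling
  distribution has relative sd ≈ 1/√(2·14) ≈ 19 % (a χ²₁₄ information
  limit), regardless of how many settings are pooled, so single-study
  inter-subject variability estimates carry ~±40 % two-sd bands. The
  within-scan and intra-subject levels, with hundreds of effective
  degrees of freedom, are far tighter.
- Raw residual RMS values are mildly biased: within-scan RMS understates
  σ_section by the factor √(1−1/7) ≈ 0.93, and higher levels inherit
  leakage from the levels below (e.g. the scan-level residual variance is
  (1−1/3)(σ_scan² + σ_section²/7)). The pipeline reports the RMS as
  defined, without moment corrections.
- The Gamma-GLM χ² assumption holds exactly only for normal residuals
  with equal group sizes; the LRT p-values are asymptotic.
- Phantom realism limits are listed above; in particular the focus gain
  map is a calibration, so focus-arm simulations reproduce the *ordering*
  and rough magnitude of defocus effects, not scanner optics.
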