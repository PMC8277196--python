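# Methods

## The measurement model

`punctakit` quantifies punctate immunofluorescence in confocal images of
single cells. The unit of analysis is one cell, one channel: a z-stack
of calibrated 2-D images (µm per pixel attached to every grid). The
chain is

1. **Overlay.** The stack is collapsed by maximum-intensity projection.
   Puncta are sparse and bright, so the per-pixel maximum preserves each
   punctum's peak regardless of its home slice; a sum projection is
   available (`projection="sum"`) for dense or dim signal.
2. **8-bit conversion.** Per-image linear min–max rescale to [0, 255]
   with round-half-up; a constant image maps to zero. Because the
   rescale is per-image, a fixed threshold's meaning depends on the
   image's dynamic range — the conversion mode is recorded in provenance
   for exactly this reason.
3. **White top-hat.** `WTH(I) = I − (I ∘ B)` with a disc structuring
   element (default radius 15 px). The opening removes every structure
   that cannot contain the disc, so the residual keeps puncta narrower
   than ~2r px and discards diffuse cytoplasmic signal and background
   gradients. The transform is nonnegative and anti-extensive
   (`0 ≤ WTH(I) ≤ I`), both asserted in tests against a brute-force
   erosion/dilation oracle.
4. **Threshold.** Foreground = intensity ≥ T (dark-background
   convention). T is a *fixed* integer held constant across experimental
   groups within a replicate; Otsu is available for exploratory runs
   only and is flagged in provenance. See "Choice of the default
   threshold" below.
5. **Particle analysis.** Connected components (8-connected by default,
   matching the common particle-analysis convention; 4-connected
   optional) with areas in µm² (`n_px · s²`), centroids in µm, and
   equivalent diameters `2√(A/π)`. `min_area_um2` defaults to 0: all
   detected puncta enter the size profiles, including those below the
   phagophore bound.

## Size classes

Vesicle identities are operationalized purely by projected area:

| class         | bounds (µm²)        | marker context |
|---------------|---------------------|----------------|
| phagophore    | (0, 0.196)          | LC3B           |
| autophagosome | [0.196, 1.767]      | LC3B           |
| lysosome      | [0.03, 0.5]         | LAMP1          |
| amphisome     | (10, ∞)             | LC3B (+EEA1)   |

plus ladder bins of 1 µm² up to “> 10” (LC3B, BECN1) and 0.1 µm² up to
“> 1” (LAMP1). Edge convention: intervals are left-closed/right-open,
except that named en-dash ranges include their printed upper bound and
“> x” classes are strictly open below; the ladder bin preceding a “> x”
class therefore closes at x. Each built-in scheme is validated as a true
partition of (0, ∞), which guarantees Σ class counts = total puncta (a
property test feeds random tables through every scheme). The
autophagosome bounds are the area images of the 0.5–1.5 µm diameter
range under `A = π(d/2)²`, echoed to three decimals (0.196, 1.767).
Overlapping named ranges (lysosome vs phagophore) never co-reside in one
scheme; schemes are marker-specific.

## Peripheral band

The cell mask is the largest connected component of an Otsu threshold
applied to a Gaussian-smoothed copy (σ = 2 µm), holes filled; a blank
field or a rival second component (≥ 50% of the largest) is an error —
each image is assumed to hold exactly one cell. A user-supplied mask
overrides estimation. The outer band of width w (default 10 µm) is
`mask − erosion(mask, disc(w/s))` with the radius rounded to whole
pixels; an equivalent distance-transform formulation (`EDT ≤ w/s`) is
kept as an independent cross-check and the two agree exactly on disc
footprints. Band membership of a punctum is decided by its **centroid**
(unambiguous for large puncta straddling the band edge); any-pixel
overlap is available behind a flag. The peripheral readout selects
puncta with area strictly > 10 µm²; with none present the fraction is
reported as missing, never as zero. For a circular cell of radius R with
centroids placed uniformly, the expected band fraction is the annulus
ratio `1 − ((R−w)/R)²` (≈ 0.462 for R = 37.5, w = 10), which the
generator reproduces within binomial sampling error.

## Colocalization

Pearson correlation of two co-registered channels with **no intensity
threshold**, computed after applying the same white top-hat to each
channel (radii independently settable, equal by default). The default
ROI is the estimated cell mask: background pixels outside the cell are
jointly dark in both channels and would inflate r; whole-frame mode is
kept for parity with common plugin defaults and recorded in the result.
A third mode restricts the ROI to the union of > 10 µm² puncta from a
reference-channel table. r is reported missing when a channel is
constant over the ROI. Manders coefficients, Costes randomization and
thresholded Pearson variants are deliberately out of scope. Percent
change between conditions is `100·(r_ctrl − r_treat)/r_ctrl`, signed so
an increase under treatment is negative, and rounded only for report
echo.

## Group statistics

Cells (oocytes) are the statistical unit. Values are normalized to the
reference group's mean (reference normalizes to exactly 1), summarized
as mean ± SEM (`sd(ddof=1)/√n`), and compared with a two-tailed unpaired
Student's t-test (equal-variance; Welch behind a flag) or one-way ANOVA
followed by Tukey HSD (Bonferroni optional). Significance markers follow
*P < 0.05, **P ≤ 0.01; compact significance letters are assigned
greedily so that groups sharing no letter differ in the post-hoc test.
Dose-response summaries carry per-dose mean area, mean count and
viability; a dose with viability below 50% is excluded from the ANOVA
with an explicit toxicity reason rather than analysed. Calibration is
tested: under a simulated Gaussian null (10,000 replicates) the
two-group test rejects at α = 0.05 with empirical rate 0.05 ± 0.01, and
ANOVA on two groups reproduces t² to 1e-9.

## Synthetic data: what it emulates, and what it does not

The generator emulates the imaging regime the pipeline targets: one
~75 µm oocyte per field with a 25 µm nucleus, a 15-slice z-stack at 1 µm
spacing, bright puncta from ~0.03 µm² to > 10 µm², Poisson shot noise
plus Gaussian read noise. Geometry and population defaults that the
imaging literature does not pin down were fixed once as conventions:

| parameter         | default     | rationale                                    |
|-------------------|-------------|----------------------------------------------|
| µm per pixel      | 0.25        | typical 60× confocal sampling                 |
| field             | 384² px     | 96 µm, holds a 75 µm cell with margin         |
| cell / nucleus    | 75 / 25 µm  | mature mouse oocyte scale                     |
| punctum peaks     | 150–170 AU  | bright immunostaining over 25 AU cytoplasm    |
| lateral PSF σ     | 0.1 µm      | ≈ 0.23 µm FWHM of a high-NA 60× objective     |
| axial σ           | 0.75 µm     | punctum visible on ±1–2 neighbouring slices   |
| noise             | Poisson + Gaussian (sd 2) | shot + read noise, separable   |

Puncta are **Gaussian-blurred hard discs**, not Gaussian spots: the
pipeline measures projected area, so fixtures need an area-true object.
Each punctum records its requested equivalent area πr² *and* its
rendered pixel area (the disc rasterized by the pixel-center rule, with
a one-pixel floor for sub-resolution puncta). Pipeline area-recovery is
asserted against the rendered pixel area; the convergence of rendered
area to πr² is a separate generator property checked on a fine grid
(0.05 µm/px, 5% tolerance), because at working resolution the
discretization of a 4-pixel punctum alone exceeds 10%. Each punctum
lives on one home slice and attenuates into neighbours by a Gaussian
axial profile, so the overlay stage is exercised nontrivially. Placement
is uniform over the cytoplasmic annulus (or the whole disc on request)
with a hard-core separation (default 2 µm) so planted puncta remain
individually resolvable; the peripheral-cohort generator with
`peripheral_bias=None` drops both the separation and the containment
margin so centroid placement is *exactly* uniform and the annulus law
holds analytically.

Not emulated: optics-accurate PSFs, spectral bleed-through, acquisition
filtering, clumped or touching vesicles, intensity heterogeneity within
a punctum, autofluorescence texture. Passing planted-truth tests
therefore demonstrates the correctness of the measurement chain on
well-separated area-true objects, not segmentation performance on
adversarial real-world images.

## Choice of the default threshold

The method's own rule is to pick the fixed threshold that best
represents the puncta of the image and hold it constant across groups.
For the synthetic defaults this package ships T = 110: after top-hat on
the 8-bit scale, punctum peaks sit near 210–250, and a threshold at
roughly half that height cuts each blurred disc at its half-maximum —
the FWHM criterion, which recovers the rendered disc boundary and hence
the true area. A much lower threshold would include the PSF skirt and
systematically inflate areas; a much higher one would drop the dimmest
sub-resolution puncta. With default noise, T = 110 sits ≈ 8 noise
standard deviations above the filtered background, so spurious
single-pixel detections are negligible while recall for puncta ≥ 0.196
µm² stays ≥ 95%. On real data T must be re-chosen per replicate; it is
always echoed in provenance.

## Numerical conventions and degenerate inputs

- Round-half-up in 8-bit conversion (`floor(x + 0.5)`).
- Thresholds compare with ≥; raising T never grows the mask (tested).
- Erosion radii and centroid-to-pixel lookups round to nearest pixel.
- Empty cases are explicit: empty mask → empty table; no large puncta →
  missing fraction; constant channel → missing r; blank field → error.
- Determinism: every generator consumes a `numpy` `Generator` seeded
  from the caller's integer; identical (spec, seed) gives bit-identical
  stacks, and `run_experiment` reruns are byte-identical per file.
- Experiment sub-seeds are derived as
  `seed·1_000_003 + group·10_000 + cell·10 + channel (mod 2³¹)`.

## Problem sizes used by the shipped checks

Test and acceptance workloads are sized for a single CPU: 80-punctum
cells on 384² fields (three seeds per regime), 2,000 Monte-Carlo
centroids for the annulus law, a 3-point colocalization sweep with three
seeds per point, 10,000 null replicates for test calibration, and a
4-cells-per-group, two-channel young-vs-aged cohort for the end-to-end
planted-effect check. These sizes keep the full suite in the low
minutes while leaving every statistical check comfortably powered.

## Known limitations

- The 2-D projection deliberately ignores axial structure; true 3-D
  (voxel) segmentation is out of scope.
- A fixed global threshold cannot be simultaneously optimal for
  sub-resolution and large puncta under strong intensity heterogeneity;
  the generator's tight peak range reflects uniformly stained vesicles.
- The cell mask derives from the analyzed channel's diffuse signal; a
  marker with no cytoplasmic component needs a user-supplied mask.
- The erosion-based band assumes a roughly convex cell; for highly
  irregular masks the distance-transform band is the safer definition.
- Compact-letter assignment is greedy and may not be minimal in letter
  count for pathological p-value patterns (it is correct in the sense
  that groups sharing no letter are significantly different).
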