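# Methods

## The biomarkers

`tilmorph` quantifies four interpretable tumor-microenvironment biomarkers
from a per-slide multi-class tissue segmentation (labels: background,
tumor, stroma, lymphocytes, necrosis, fat, rest) with known isotropic
pixel spacing, plus optional mitosis point detections:

- **cTILs** = lymphocytes / (lymphocytes + stroma), both measured inside
  the *tumor bulk*. It emulates visual stromal-TIL scoring, where the
  pathologist estimates the lymphocyte share of the intratumoral stroma.
- **LTR** = lymphocytes / (lymphocytes + tumor), measured over all
  tumor-bearing cores of the slide.
- **ITR** = tumor within the interaction distance of lymphocytes / tumor —
  the fraction of tumor that is "inflamed".
- **MTR** = kept mitoses / tumor area (count per mm²).

The tumor bulk is built by morphological **closing** of the tumor mask
with a circular kernel whose radius is the clustering distance (default
100 μm), followed by **dilation** with the margin radius (default 50 μm).
Connected tumor components strictly smaller than 0.1 mm² are removed
before bulk formation ("smaller than" is strict: a component exactly at
the threshold is retained). Mitoses are kept only when surrounded by
tumor at least 20 μm wide, implemented as membership in the tumor mask
eroded by a 20 μm disk — the literal geometric reading, exchangeable with
a per-point disk test. The ITR interaction distance defaults to 80 μm and
is inclusive (distance ≤ 80 μm counts).

All five geometric parameters live in `BiomarkerConfig` in physical units
(μm, mm²), so results are independent of the raster resolution up to
rasterization error.

### Cores and case pooling

A *core* is an 8-connected component of non-background tissue. Only cores
containing at least one pixel of the (filtered) tumor mask enter the
computation; every tissue class is restricted to those cores first. A
slide without a tumor-bearing core yields an all-zero summary flagged
`no_tumor`, and all four biomarkers are *undefined* (`None` in the API,
empty cells in CSV) — undefined values propagate as missing data and are
excluded from downstream statistics rather than coded as sentinels.

Cases with several slides are pooled by summing per-slide areas and
mitosis counts and applying the ratios to the pooled sums, as if all
cores lay on one slide. Averaging per-slide ratios would over-weight
low-tumor slides (see `examples/02_case_pooling.py`).

Design choices where the procedure was genuinely open:

- The small-region filter feeds *every* biomarker denominator, not only
  the bulk construction, so one tumor definition is used throughout; a
  config switch (`apply_small_region_filter_globally`) restores raw-tumor
  denominators.
- A core counts as tumor-bearing from a single filtered-tumor pixel; no
  additional minimum tumor amount is imposed.
- All computations (including the ITR lymphocyte reference set) are
  restricted to tumor-bearing cores.
- 8-connectivity is used for components so diagonally touching nests are
  not split.
- The closing kernel radius equals the clustering distance even though a
  radius-r closing can bridge gaps approaching 2r; the construction
  follows the stated kernel, not a gap-semantics reinterpretation.
- The `no_tumor` flag survives pooling only when every slide carries it.

## Morphology implementation

Disk structuring elements are the integer pixel offsets with Euclidean
norm ≤ radius/spacing. Dilation, erosion and closing are computed through
exact Euclidean distance transforms (`scipy.ndimage.distance_transform_edt`),
which is mathematically identical to sliding the disk but linear-time:

- dilation = {p : dist(p, foreground) ≤ r}
- erosion = {p : dist(p, background) > r}, with the outside of the canvas
  treated as background,
- closing computed on a canvas padded by the kernel radius so the
  intermediate dilation is never clipped, then cropped; the result is
  always a superset of the input.

Both routes take sqrt of the same integer squared distances, so the
distance-transform implementation and a structuring-element oracle make
bit-identical inclusion decisions at the disk boundary; the test suite
verifies pixelwise equality on random masks.

Numerical conventions: a point (x, y) μm maps to pixel
(row, col) = (floor(y/s), floor(x/s)); masks with anisotropic calibration
are rejected; the mm² conversion of the small-region threshold is
compared in μm² with a sub-pixel tolerance so exact-threshold components
are kept deterministically.

## Synthetic phantoms

`generate_phantom` emulates a core-needle biopsy slide: 1–n elongated
stroma cores (default three of 6 × 1 mm), axis-aligned square tumor nests
(default four of 0.6 mm, 0.36 mm² each, 150 μm apart so the default
clustering distance bridges them), compact 40 μm lymphocyte clusters
placed inside the bulk, and mitoses planted on the perimeter of each
nest's inset rectangle so every point lies at an exact, controlled
distance from the tumor boundary. Nests are distributed over all cores
but the last, so multi-core phantoms always exercise the tumor-free-core
exclusion. All randomness comes from a single seed; identical specs give
bit-identical outputs.

Ground truth is computed in continuous micron space with polygon geometry
(shapely): the bulk is `buffer(+r).buffer(−r).buffer(margin)`, the
inflamed tumor is the tumor intersected with the 80 μm lymphocyte buffer,
and the lymphocyte target area is solved exactly so that the ground-truth
cTILs equals the requested `lymphocyte_fraction_in_bulk`. For a single
convex nest the bulk area reduces to the closed form
L·W + 2(L+W)r + πr². The ground truth never touches the raster pipeline,
making it an independent oracle for end-to-end tests.

Rasterization places a pixel in a shape iff its center falls inside the
half-open rectangle. Phantom rectangles and cluster sites are laid out on
a 4 μm quantum so their edges coincide with pixel boundaries at the 2 and
4 μm spacings used in testing; then rasterized areas and distance fronts
track the continuous geometry closely. Remaining systematic error is
sub-pixel: at 2 μm spacing the pipeline recovers the constructive
biomarkers to well within 2% (ITR is the worst at ≈1.6%, from curvature
bias where the 80 μm lymphocyte front bends around cluster corners). At
4 μm the 50 μm margin is 12.5 px and the half-pixel front bias grows to a
few percent; 2 vs 4 μm biomarker differences stay below 5%. What phantoms
do **not** emulate: irregular nest shapes, texture, staining variation,
segmentation noise, in-situ vs invasive distinction — so passing tests
demonstrate correctness of the *geometry and statistics*, not robustness
to imperfect upstream segmentations.

## Cohort simulation and statistics

`generate_cohort` draws a latent biomarker b ~ N(0,1) per case, links it
to pathological complete response through
logit P(pCR|b) = α + β·b (β = `effect_size`), with α solved by numerical
integration so the marginal responder fraction matches (default 0.30,
typical of mixed neoadjuvant cohorts), and adds N(0, noise_sd²)
observation noise. Clinical covariates (age, grade, T/N stage, subtype)
are drawn independently. The AUC implied by the generative model is
available via numerical integration of the class-conditional score
densities (`analytic_auc`), used to check calibration: across 100
replicates at n = 500 the DeLong 95% CI covers the generative AUC ≈95%
of the time.

The evaluation layer mirrors standard biomarker methodology:

- visual-TIL case scores average slide scores per pathologist, then
  across pathologists; a case is unscorable when any pathologist has no
  scorable slide;
- biomarkers are dichotomized at their median (ties to the low group; the
  tie direction is a convention), except MTR which splits at 0 vs > 0
  because most slides carry no kept mitosis;
- AUC is the tie-corrected Mann–Whitney statistic; CI and p-value (vs
  0.5) use DeLong's structural-components method, with a stratified
  bootstrap available behind a flag. The choice of DeLong is a
  convention; no particular CI method is canonical here.
- the confounder screen adds one covariate at a time to the unadjusted
  logistic model and retains it iff the biomarker odds ratio changes by
  ≥ 10% relative to the model without it (forward single-addition;
  decisions are therefore order-independent); the final model holds the
  biomarker plus all retained confounders, with per-variable Wald tests.
  Grade is never tested for MTR, since mitotic count is a grading
  component. Complete cases across all candidates are used so nested odds
  ratios are comparable. Quasi-separation or non-convergence is reported
  as "adjusted model not computable", never silently dropped.
- p-values are not corrected for multiple testing.

## Problem sizes and limitations

Tests and the acceptance script run on phantoms of roughly 1–7 million
pixels (2–4 μm spacing), 50 random 128² masks for the morphology oracle,
and simulated cohorts of 120–4000 cases; the full suite completes in well
under a minute on one CPU. Known limitations: only isotropic spacing is
supported; the mitosis surround test uses the filtered tumor mask, so
mitoses in sub-threshold tumor islands are always dropped; phantom
lymphocyte fractions above ≈0.5 are geometrically unreachable with
disjoint 40 μm clusters and raise an error; and none of the statistics
module addresses survival endpoints.
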