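# Methods

## Measurement model

Telomere-specific FISH probes hybridize in proportion to telomere repeat
length, so at constant exposure the integrated Cy3 fluorescence of a
telomeric spot is a linear proxy for the telomere's length. The per-cell
estimate is the telomere fluorescence intensity

    TFI = Σ_spots (I · A) / D

where `I` is a spot's mean Cy3 intensity measured on the normalized but
otherwise unfiltered image, `A` its segmented area (so `I·A` is the spot's
integrated signal in AU·px), and `D` the cell's total DAPI signal. Dividing
by `D` normalizes for DNA content, ploidy, and nuclear truncation by the
section plane.

Absolute TFI is not comparable across slides (staining efficiency and
exposure vary), so cross-specimen analyses use the per-image
epithelial/stromal ratio `R = TFI_epi / mean(TFI_stromal, same image)`:
stromal cells act as an internal reference of the same slide, same
hybridization, same exposure. The ratio is computed strictly per image —
an image with no stromal cells is an error, never silently referenced to
cohort-level stroma. Specimen summaries are cell-pooled means (every cell
weighs the same, not every image).

TLV, the cell-to-cell telomere length variation, is the sample standard
deviation (n−1) of the per-cell value within one specimen. It is computed
on raw TFI by default with a config switch to the ratio scale
(`metrics.tlv_value`). The choice matters: TLV on TFI carries the intensity
scale, TLV on ratios is dimensionless near 1; published TLV magnitudes in
the tens are only consistent with an intensity-like scale, but both
conventions are supported rather than silently resolved.

## Measurement chain and its contracts

1. **Background subtraction** (`subtract_background`): constant or
   image-percentile estimate, clamped at zero. Default: the median
   (50th percentile), a robust background estimate when cells cover a
   minority of the field. Both channels are normalized this way before any
   measurement; otherwise the additive camera/autofluorescence offset
   inflates every spot value by `offset·A` and every DAPI total by
   `offset·area(ROI)`, a bias that does not cancel between compartments.
2. **Sharpening** (`sharpen`): 3×3 unsharp mask `img − amount·∇²img`,
   clamped at zero; default amount 0.5. Amount 1 amplifies shot noise
   roughly five-fold and mostly raises the noise floor; 0.5 keeps spot
   contours crisp at half the noise penalty.
3. **Rolling-ball enhancement** (`rolling_ball`): subtracts the grayscale
   opening of the image with a spherical-cap structuring function
   (radius 5 px by default — comfortably wider than a diffraction-limited
   spot, narrower than nuclear-scale background). Implemented with exact
   grayscale morphology (±inf boundary handling, so out-of-bounds pixels
   are ignored rather than reflected); the test suite checks bit-level
   agreement with a brute-force opening oracle.
4. **Segmentation** (`segment_spots`): threshold + connected components
   (8-connectivity default) + area filter [2, 1000] px. The default
   threshold is a noise-floor cut at `k·σ` (k = 6) with σ estimated from
   the sub-90th-percentile enhanced pixels. Otsu is available but is a poor
   default for spot images: with a huge near-zero background class and a
   small bright foreground class it lands near half the spot peak scale and
   discards the dim flanks of weak spots — a loss that is *differential*
   between bright and dim compartments and therefore biases the
   epithelial/stromal ratio itself. A noise-anchored threshold keeps the
   flux loss small and nearly brightness-independent. The upper area bound
   exists to reject non-spot artifacts; it is set well above the largest
   plausible merged spot cluster, because removing a merged cluster deletes
   all of its flux.
5. **Extraction** (`extract_spots`): every component is measured on the
   normalized Cy3 plane; enhancement shapes *which* pixels are measured,
   never the measured values. A spot belongs to the ROI under its centroid
   (deterministic rule for spots straddling two nuclei); centroids on
   background give `cell_label` 0 and are excluded from cell totals.
6. **Aggregation** (`quantify_cells`): cells with no detected spots are
   retained with TFI 0; cells with non-positive DAPI totals are excluded
   with a warning. An optional `tfi.scale` display multiplier is recorded
   in the output config (published murine TFI values in the tens imply such
   a presentation factor; the raw ratio is the default).

## Synthetic specimen generator

The generator emulates the study conditions so every downstream stage can be
validated against known truth:

- **Geometry**: epithelial nuclei as ellipses on crypt rings ("cells in
  straight array"), 8 cells per ring, rings on a collision-free grid;
  stromal nuclei scattered uniformly. Placement is rejection sampling with
  200 attempts per cell, then an error naming the compartment. Defaults:
  1024×1024 px field, nuclear radius 24 ± 2 px — the scale of 100×
  magnification, where a diffraction-limited telomeric spot (rendered as a
  Gaussian blob of σ 1.5 px) is small against the nucleus.
- **Signal**: per-cell spot count Poisson(15); per-spot integrated signal
  lognormal(log 3·10⁴, 0.5) AU·px; per-nucleus DAPI total
  lognormal(log 2.5·10⁶, 0.2) AU spread uniformly over the nucleus.
  Compartment contrasts (e.g. epithelial/stromal ratio, mucus boost) shift
  the lognormal log-mean, leaving shape untouched. Spot blobs are
  normalized so their *integrated* (not peak) intensity equals the drawn
  signal, and their footprint is confined to the nucleus mask — hence with
  no PSF/noise the Cy3 integral over a cell's ROI equals
  `T_true · exposure_gain` exactly, the anchor for exactness tests.
- **Mucus (goblet) cells**: circular low-DAPI vacuole holes rendered in the
  DAPI channel only; the hole's signal is redistributed so the nuclear
  total stays `D_true` (appearance changes, truth does not), and ROI labels
  are untouched, mirroring classification by look rather than mask
  geometry.
- **Acquisition**: Gaussian PSF (σ 1 px) → per-channel exposure gain →
  additive background (offset 150 AU + 0.05 AU/px gradient along x) →
  optional Poisson shot noise → Gaussian read noise (SD 5 AU) → clipping to
  the 16-bit range. If clipping touches >1% of signal pixels a warning is
  raised and logged. With shot noise the background SD is ~12 AU while
  default spot peaks are several hundred AU — bright-spot imaging, as qFISH
  exposure protocols aim for.
- **Reproducibility**: one integer master seed; per-specimen sub-seeds are
  spawned from a `numpy SeedSequence` and recorded in the manifest;
  identical spec + seed reproduces bit-identical images and truth.

What the generator does **not** emulate: 3-D stacks, chromatic aberration,
tissue folds, uneven hybridization, overlapping/touching nuclei, or
segmentation errors in the ROI masks (masks are inputs here, as they were
hand-drawn in the original workflow). Passing recovery tests therefore
demonstrate correctness of the measurement chain under clean ROIs and
well-behaved optics, not robustness to histology artifacts.

## Statistics

- Two-sample t-tests exist in raw-data and summary-statistic forms; the raw
  form is by construction the summary form applied to the samples' own
  summaries, exactly. The default unpaired variant is the pooled Student
  test (the era's common default); Welch with Satterthwaite df is available
  everywhere. All p-values are two-sided.
- Degenerate inputs follow explicit conventions (both SDs zero: p = 1 for
  equal means, p = 0 otherwise; identical nonzero paired differences:
  p = 0), each logged.
- One-way ANOVA reports F with (k−1, N−k) df; with two groups F = t² of the
  pooled test. Tukey's HSD uses the studentized range distribution with
  (k, N−k) parameters and the Tukey–Kramer standard error for unbalanced
  groups; at k = 2 it reproduces the pooled t-test p exactly. The
  studentized range CDF comes from scipy's numerically integrated
  implementation and is cross-checked in the tests against an independent
  integration oracle.
- `pooled_group_summary` combines printed (mean, SD, n) triples exactly as
  if the raw observations had been concatenated.
- Count conventions: immunostain scores are positive:*negative* ratios (not
  positive fractions), and organoid counts are rescaled by the factor that
  maps the starting count to 100.

## Problem sizes and numerical choices

The test suite and acceptance script validate recovery on cohorts of 2 × 5
specimens with ~100 cells per specimen at 1024² px — enough cells
(≥ 50 epithelial, ≥ 20 stromal per image) for per-specimen ratio standard
errors of a few percent, at desk-scale runtimes. Recovery is judged against
the *realized* truth-table values rather than the nominal generator
parameters: with 5 specimens the realized cohort mean ratio itself
fluctuates a few percent around the nominal setting, and the pipeline
should be held to what was actually rendered. Unit tests use smaller fields
(512², radius-12 nuclei) where exactness, not realism, is at stake.

Numerical tie-breaks and tolerances: morphology uses exact float
comparisons with ±inf boundary values; spot-to-cell assignment rounds the
centroid to the nearest pixel; percentile background uses numpy's linear
interpolation; TFI recovery assertions use 10% relative tolerance under
default noise and 1% in the noise-free exactness regime (with sharpening
disabled there, since the unsharp clamp intentionally discards sub-zero
flank pixels).

## Known limitations

- Threshold segmentation always loses some sub-threshold tail flux
  (~1–5% under defaults); it largely cancels in ratios but makes absolute
  TFI a slight underestimate.
- The rolling-ball step is not scale-equivariant (ball heights are in
  intensity units), so rescaling an image rescales TFI only approximately
  when the threshold is re-estimated; with a fixed footprint the
  measurement is exactly linear.
- Stromal referencing assumes stromal telomere biology is stable across
  the compared groups; the package computes, but cannot validate, that
  assumption.
- No automatic nuclear segmentation: ROI label masks are inputs by design.
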