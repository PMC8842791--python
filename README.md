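# telofish

Quantitative telomere FISH (qFISH) image analysis for tissue sections: from
two-channel fluorescence microscopy images to per-cell telomere length
estimates, specimen-level biomarkers, and group statistics.

## The problem

Telomere attrition is an early event in the metaplasia–dysplasia–carcinoma
sequence of Barrett's esophagus and in telomerase-deficient mouse models of
it. In situ qFISH measures telomere length cell by cell in intact tissue: a
Cy3-labelled telomere-specific probe produces fluorescent spots whose
integrated intensity is linearly proportional to telomere length at constant
exposure, and a DAPI counterstain measures each nucleus's total DNA content.

`telofish` implements the full measurement chain used in such studies:

- **TFI (telomere fluorescence intensity)** per cell
  `TFI = Σ_spots (I·A) / D`, where `I·A` is a telomeric spot's mean Cy3
  intensity times its area (its integrated signal) and `D` the total DAPI
  signal of the cell's nuclear ROI — the per-cell telomere length proxy,
  normalized for DNA content and ploidy.
- **Epithelial/stromal ratio** `R = TFI_epi / mean(TFI_stroma)` computed per
  image, using the stromal cells of the *same image* as an internal
  reference that cancels staining and exposure variation between specimens.
- **TLV (telomere length variation)**: the sample standard deviation of the
  per-cell telomere value within one biological specimen — low TLV flags
  loss of cell-to-cell heterogeneity, a signature of clonal expansion.
- **Group statistics**: unpaired (pooled/Welch) and paired t-tests — in both
  raw-data and summary-statistic (`mean ± SD, n`) forms — one-way ANOVA with
  Tukey's HSD post-hoc test, pooled group summaries, positive:negative cell
  ratios for immunostain scoring, and organoid count normalization.

Because published raw images are rarely deposited, the package ships a
**synthetic qFISH generator**: crypt-arranged epithelial nuclei vs scattered
stromal nuclei, lognormal per-spot signal, DAPI rendering with goblet-cell
vacuoles, PSF blur, background gradient, and Poisson–Gaussian noise — with a
per-cell ground-truth table, so the whole chain is verifiable end to end.

## Worked example

Reproducing comparisons from printed summary statistics
(`examples/04_group_stats_from_summaries.py`):

```python
from telofish import GroupSummary, t_from_summary, pooled_group_summary

damage = t_from_summary(GroupSummary(0.36, 0.13, 8),
                        GroupSummary(0.22, 0.09, 8), "student")
# t = 2.50, df = 14, p = 0.025

ratio = t_from_summary(GroupSummary(0.87, 0.23, 8),
                       GroupSummary(0.45, 0.18, 5), "welch")
# t = 3.67, df = 10.2, p = 0.0041

pooled = pooled_group_summary([GroupSummary(2.67, 1.00, 9),
                               GroupSummary(2.25, 1.04, 8)])
# 2.47 ± 1.01 SD (n = 17)
```

The first result says marker-positive:negative cell ratios of 0.36 vs 0.22
across 8 animals per group differ significantly (p = 0.025); the second that
epithelial/stromal telomere ratios of 0.87 (healthy tissue, n = 8) vs 0.45
(metaplasia, n = 5) differ at p = 0.004 under Welch's correction for unequal
variances; the third pools two printed per-time-point summaries into one
group exactly as if the raw scores had been concatenated.

Measuring a simulated image pair (`examples/02_quantify_image.py`):

```text
detected 2714 spots across 52 cells
 epithelial: measured TFI 0.1828  true 0.1853  recovery 98.7%
    stromal: measured TFI 0.2031  true 0.2056  recovery 98.8%
```

`quantify_image` recovers ~99% of the generator's true per-cell signal
ratio `T_true/D_true`; the remaining shortfall is spot-tail flux below the
segmentation threshold, which cancels in the epithelial/stromal ratio.

A configured end-to-end run (`examples/05_full_pipeline.py`, or
`telofish run --config config.yaml`) writes `cells.csv`, `spots.csv`,
`specimens.csv`, `ratios.csv`, `tests.csv`, a markdown report, the effective
config, and a run log with every warning.

## Layout

- `src/telofish/simulate.py` — synthetic qFISH specimen/cohort generator
- `src/telofish/quant.py` — spot detection and per-cell TFI measurement
- `src/telofish/metrics.py` — ratios, specimen means, TLV, subtype means
- `src/telofish/stats.py` — t-tests, ANOVA, Tukey HSD, pooled summaries
- `src/telofish/pipeline.py`, `cli.py` — configured orchestration + CLI
- `examples/` — one short narrative script per capability
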