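"""Run the telomere-spot measurement chain on a simulated image pair and
compare measured TFI against the generator's ground truth.

The chain: background subtraction -> sharpening -> rolling-ball enhancement
-> spot segmentation -> per-spot measurement on the normalized image ->
per-cell TFI = (sum of spot values) / (DAPI total of the cell's ROI).
"""

from telofish import (SpecimenSpec, default_acquisition, default_compartments,
                      quantify_image, simulate_specimen)

spec = SpecimenSpec("demo", "cardia", default_acquisition(),
                    default_compartments(n_epithelial=32, n_stromal=20),
                    seed=3)
cy3, dapi, labels, truth = simulate_specimen(spec)

spots, cells = quantify_image(cy3, dapi, labels)
print(f"detected {len(spots)} spots across {len(cells)} cells")

merged = cells.merge(truth, on="cell_label")
merged["true_tfi"] = merged["T_true"] / merged["D_true"]
for comp, grp in merged.groupby("compartment"):
    measured, true = grp["tfi"].mean(), grp["true_tfi"].mean()
    print(f"{comp:>11}: measured TFI {measured:.4f}  true {true:.4f}  "
          f"recovery {100 * measured / true:.1f}%")
# Recovery near 100% means the segmentation footprint captures nearly all
# telomeric flux; the few percent shortfall is tail flux below the noise
# threshold, which cancels when TFI enters an epithelial/stromal ratio.
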