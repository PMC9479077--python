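"""Simulate a FLIM image of a yeast-cell field, segment it, render the map.

A 20-cell field is generated with per-cell biological variability of
(a1, tau_bound), segmented by Otsu + connected components, every cell's
pooled histogram is fitted, and the pseudocolor lifetime map (1.5-4.0 ns
blue->red) is written as PNG.
"""

import numpy as np

from flimredox import (
    FieldLayout,
    fit_rois,
    render_lifetime_map,
    segment_cells,
    simulate_field,
    species_preset,
    summarize_group,
)

preset = species_preset("kmarxianus")
layout = FieldLayout(image_shape=(256, 256), n_cells=20, seed=21)
stack, truth = simulate_field(preset, layout)
print(f"simulated {len(truth)} cells, {stack.counts.sum():,} photons total")

labels, records = segment_cells(stack)
print(f"segmented {len(records)} cells (ground truth: {len(truth)})")

fitted = fit_rois(stack, labels, records)
summary = summarize_group(fitted, "tau_mean", label="kmarxianus")
print(f"per-cell tau_mean: {summary.mean:.3f} +/- {summary.sd:.3f} ns over n={summary.n} "
      "(population target 1.21 +/- 0.27 ns)")

render_lifetime_map(fitted, labels, out_path="lifetime_map.png")
print("wrote lifetime_map.png — each cell coloured by its fitted tau_mean")
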