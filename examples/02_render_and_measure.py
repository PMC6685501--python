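"""Render brightfield/fluorescence images for a few cells and re-measure them.

Each cell becomes three 16-bit rasters (brightfield + green/red
acridine-orange channels).  The morphometry chain segments the head and
recovers the six features; the DFI comes back from the channel maxima.
"""

import numpy as np

import spermdfi as s
from spermdfi.pipeline import measure_image_table

cfg = s.SyntheticConfig(n_cells=5, seed=2, noise_sd=0.0, donor_shift_sd=0.0)
table, truth = s.generate_feature_table(cfg)
images = list(s.generate_image_cohort(table, truth, cfg))
measured = measure_image_table(images)

print(f"{'feature':>8s} {'true':>8s} {'measured':>9s} {'rel err %':>9s}")
for f in list(s.FEATURES) + ["DFI"]:
    t, m = table[f].iloc[0], measured[f].iloc[0]
    print(f"{f:>8s} {t:8.4f} {m:9.4f} {100 * (m / t - 1):9.2f}")
print("-> the imaging round trip recovers each morphological parameter to a")
print("   few percent and the fluorescence-ratio DFI almost exactly.")
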