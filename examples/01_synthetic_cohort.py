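"""Generate a synthetic single-sperm cohort and summarize its DFI.

Draws the default study-sized cohort (1056 cells, six donors) whose
Ln(DFI) follows the published morphology model plus donor shifts and
calibrated noise, then prints the feature means and the shape of the DFI
distribution.
"""

import numpy as np

import spermdfi as s

cfg = s.SyntheticConfig(n_cells=1056, seed=0)
table, truth = s.generate_feature_table(cfg)

print(f"cells: {len(table)}, donors: {table['donor'].nunique()}")
print("feature means (um / um^2 / dimensionless):")
for f in s.FEATURES:
    print(f"  {f:>3s}: {table[f].mean():7.3f}  (sd {table[f].std():.3f})")

d = table["DFI"].to_numpy()
print(f"median DFI: {np.median(d):.3f}")
frac = np.mean((d >= 0.07) & (d <= 0.15))
print(f"fraction of cells with DFI in [0.07, 0.15]: {frac:.3f}")
print("-> most cells carry mildly fragmented DNA; a small tail is worse,")
print("   which is the population structure the prediction models exploit.")
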