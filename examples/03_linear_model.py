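"""Fit the centered-interaction linear model of Ln(DFI) with forward selection.

Splits the cohort 65/10/25, selects terms from the 28-candidate set
(main effects plus all centered two-factor products) by cross-validated
R^2, and reports per-term statistics and per-split correlations.
"""

import spermdfi as s
from spermdfi.dfi import ln_dfi
from spermdfi.modeling import (
    LinearModelSpec,
    candidate_terms,
    centers_from_table,
    forward_select,
    split_data,
)

cfg = s.SyntheticConfig(n_cells=1056, seed=0)
table, _ = s.generate_feature_table(cfg)
split = split_data(table, (0.65, 0.10, 0.25), seed=0)
train = table[split.train]

spec = forward_select(train, candidate_terms(centers_from_table(train)), seed=0)
fit = s.fit_linear(train, LinearModelSpec(list(spec.terms)))

print(f"{'term':34s} {'estimate':>9s} {'SE':>7s} {'t':>7s} {'P':>8s} {'VIF':>6s}")
for i, name in enumerate(fit.spec.term_names):
    vif = "-" if name == "Intercept" else f"{fit.vifs[i]:6.2f}"
    print(f"{name:34s} {fit.estimates[i]:9.3f} {fit.std_errors[i]:7.3f} "
          f"{fit.t_ratios[i]:7.2f} {fit.p_values[i]:8.4f} {vif:>6s}")

ln = ln_dfi(table["DFI"].to_numpy())
pred = fit.predict(table)
for name in ("train", "validation", "test"):
    m = split.labels == name
    print(f"{name} r = {s.pearson_r(ln[m], pred[m]):.3f}")
print("-> circularity- and acrosome-related terms dominate; the held-out r")
print("   quantifies how much DNA integrity is predictable from shape alone.")
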