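"""Nonlinear regression and good/bad classification of sperm DNA integrity.

Trains the one-hidden-layer tanh network (Levenberg-Marquardt, early
stopping on the validation set) as the nonlinear regressor, and a
logistic classifier of the top-20% Ln(DFI) rank category, on the same
65/10/25 split.
"""

import numpy as np

import spermdfi as s
from spermdfi.dfi import ln_dfi
from spermdfi.modeling import NNConfig, fit_logistic, fit_nn, split_data

cfg = s.SyntheticConfig(n_cells=1056, seed=0)
table, _ = s.generate_feature_table(cfg)
split = split_data(table, seed=0)
ln = ln_dfi(table["DFI"].to_numpy())

reg = fit_nn(table, split, NNConfig(hidden_nodes=20, seed=0))
pred = reg.predict(table)
print(f"neural network ({reg.n_epochs} epochs):")
for name in ("train", "validation", "test"):
    m = split.labels == name
    print(f"  {name} r = {s.pearson_r(ln[m], pred[m]):.3f}")

log = fit_logistic(table, split, threshold_percentile=80, seed=0)
scores = log.predict_proba(table)
labels = log.true_labels(table)
pred_labels = log.predict_label(table)
print("logistic classifier (bad = top 20% Ln(DFI) rank):")
for name in ("train", "validation", "test"):
    m = split.labels == name
    roc = s.roc_auc(scores[m], labels[m])
    cm = s.confusion(pred_labels[m], labels[m])
    print(f"  {name}: AUC = {roc.auc:.3f}, accuracy = {cm.accuracy:.3f} "
          f"(tp={cm.tp} fp={cm.fp} tn={cm.tn} fn={cm.fn})")
print("-> AUC measures ranking quality of the good/bad split; accuracy is")
print("   dominated by the 80% majority class, so read them together.")
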