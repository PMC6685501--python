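"""Plot helpers for the standard report panels.

Each function takes already-computed report data and returns a matplotlib
Figure: actual-vs-predicted scatter, per-rank-group mean bars, enrichment
percentile bars, and ROC curves.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def _group_labels(groups) -> list[str]:
    return [f"{int(g.bounds[0])}-{int(g.bounds[1])}%" for g in groups]


def actual_vs_predicted(actual, predicted, r: float | None = None):
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(predicted, actual, s=8, alpha=0.5)
    lims = [min(np.min(predicted), np.min(actual)), max(np.max(predicted), np.max(actual))]
    ax.plot(lims, lims, "k:", lw=1)
    ax.set_xlabel("predicted Ln(DFI)")
    ax.set_ylabel("actual Ln(DFI)")
    if r is not None:
        ax.set_title(f"r = {r:.3f}")
    fig.tight_layout()
    return fig


def rank_group_means(groups):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    means = [g.mean_actual for g in groups]
    ax.bar(range(len(groups)), means)
    ax.set_xticks(range(len(groups)), _group_labels(groups), rotation=45)
    ax.set_xlabel("predicted Ln(DFI) rank group")
    ax.set_ylabel("mean actual Ln(DFI)")
    fig.tight_layout()
    return fig


def enrichment_percentiles(groups):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    vals = [g.enrichment_percentile for g in groups]
    ax.bar(range(len(groups)), vals)
    ax.axhline(50, color="k", ls=":", lw=1)
    ax.set_xticks(range(len(groups)), _group_labels(groups), rotation=45)
    ax.set_xlabel("predicted Ln(DFI) rank group")
    ax.set_ylabel("enrichment percentile of median actual Ln(DFI)")
    fig.tight_layout()
    return fig


def roc_curves(curves: dict):
    """``curves`` maps a split name to a ROCCurve."""
    fig, ax = plt.subplots(figsize=(4, 4))
    for name, roc in curves.items():
        ax.plot(roc.fpr, roc.tpr, label=f"{name} (AUC = {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    return fig
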