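"""Scoring of DFI predictions: correlation, rank groups, enrichment, ROC.

Predictions are evaluated the way the study frames them: Pearson r
between actual and predicted Ln(DFI), percentile rank groups of the
predicted values (0-5, 5-10, 10-20, 20-80, 80-90, 90-95, 95-100 by
default), Welch t-tests of each group's actual Ln(DFI) against the whole
test set, an enrichment percentile per group (where a group's median
actual Ln(DFI) sits within the full test set under a quality ordering:
higher percentile = lower DFI = better), ROC/AUC and confusion matrices
for the rank classifier, and leave-one-donor-out testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dfi import ln_dfi
from .errors import ConfigurationError, DegenerateInput, SchemaError

logger = logging.getLogger(__name__)

#: Percentile rank-group bounds used throughout the analysis.
DEFAULT_RANK_BOUNDS: tuple[tuple[float, float], ...] = (
    (0, 5), (5, 10), (10, 20), (20, 80), (80, 90), (90, 95), (95, 100),
)


def pearson_r(actual, predicted) -> float:
    """Sample Pearson correlation between actual and predicted values."""
    x = np.asarray(actual, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape:
        raise DegenerateInput("actual and predicted must have the same length")
    if x.size < 3:
        raise DegenerateInput("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInput("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# rank groups
# ---------------------------------------------------------------------------

@dataclass
class RankGroupAssignment:
    """Group index per input record, under ascending predicted rank."""

    bounds: tuple[tuple[float, float], ...]
    group_index: np.ndarray  # per original record
    n: int

    def members(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.group_index == g)


def _validate_bounds(bounds) -> tuple[tuple[float, float], ...]:
    bs = tuple((float(lo), float(hi)) for lo, hi in bounds)
    ordered = sorted(bs)
    if not ordered or ordered[0][0] != 0 or ordered[-1][1] != 100:
        raise ConfigurationError(f"bounds must cover [0, 100], got {bs}")
    for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
        if hi1 != lo2:
            raise ConfigurationError(f"bounds must tile [0, 100] without gaps/overlap: {bs}")
    for lo, hi in bs:
        if hi <= lo:
            raise ConfigurationError(f"empty bound ({lo}, {hi})")
    return bs


def rank_groups(predicted, bounds=DEFAULT_RANK_BOUNDS) -> RankGroupAssignment:
    """Assign cells to percentile groups of predicted Ln(DFI), low to high.

    Cells are sorted ascending by prediction (stable, so ties keep input
    order); the cell at 0-based rank i falls in group (lo, hi] when
    ``lo < 100 * (i + 1) / n <= hi``.
    """
    bs = _validate_bounds(bounds)
    p = np.asarray(predicted, dtype=float)
    n = p.size
    if n == 0:
        raise DegenerateInput("no predictions to rank")
    order = np.argsort(p, kind="stable")
    q = 100.0 * (np.arange(n) + 1) / n
    group_of_rank = np.empty(n, dtype=int)
    for g, (lo, hi) in enumerate(bs):
        group_of_rank[(q > lo) & (q <= hi)] = g
    group_index = np.empty(n, dtype=int)
    group_index[order] = group_of_rank
    return RankGroupAssignment(bounds=bs, group_index=group_index, n=n)


@dataclass
class RankGroupSummary:
    """Statistics of one predicted-rank group on the actual Ln(DFI)."""

    bounds: tuple[float, float]
    n: int
    mean_actual: float
    t_stat: float
    p_vs_overall: float
    test_skipped: bool
    enrichment_percentile: float | None = None

    def to_dict(self) -> dict:
        return {
            "bounds": list(self.bounds), "n": self.n,
            "mean_actual": self.mean_actual, "t_stat": self.t_stat,
            "p_vs_overall": self.p_vs_overall, "test_skipped": self.test_skipped,
            "enrichment_percentile": self.enrichment_percentile,
        }


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unpaired two-tailed t-test: (t, p, Welch-Satterthwaite dof)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    denom = va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1)
    dof = (va + vb) ** 2 / denom if denom > 0 else np.nan
    return float(res.statistic), float(res.pvalue), float(dof)


def group_mean_and_test(assignment: RankGroupAssignment,
                        actual) -> list[RankGroupSummary]:
    """Per-group mean actual Ln(DFI) and Welch test against the full set."""
    y = np.asarray(actual, dtype=float)
    if y.size != assignment.n:
        raise SchemaError("actual values must match the ranked cohort")
    out = []
    for g, bound in enumerate(assignment.bounds):
        members = assignment.members(g)
        vals = y[members]
        if members.size < 2:
            out.append(RankGroupSummary(bound, int(members.size),
                                        float(vals.mean()) if members.size else np.nan,
                                        np.nan, np.nan, True))
            continue
        t, p, _ = welch_t(vals, y)
        out.append(RankGroupSummary(bound, int(members.size), float(vals.mean()),
                                    t, p, False))
    return out


def enrichment_percentile(group_actual, all_actual,
                          higher_is_better: bool = False) -> float:
    """Percentile of the group's median actual Ln(DFI) within the cohort.

    Under the default quality ordering lower Ln(DFI) is better, so the
    percentile counts how many of the cohort's values are *worse* (higher)
    than the group median, with mid-rank handling of ties; a group of
    low-DFI cells therefore scores above 50.  ``higher_is_better`` flips
    the ordering.
    """
    g = np.asarray(group_actual, dtype=float)
    ref = np.asarray(all_actual, dtype=float)
    if g.size == 0 or ref.size == 0:
        raise DegenerateInput("empty group or reference set")
    m = float(np.median(g))
    if higher_is_better:
        worse = int((ref < m).sum())
    else:
        worse = int((ref > m).sum())
    ties = int((ref == m).sum())
    return 100.0 * (worse + 0.5 * ties) / ref.size


def rank_group_report(predicted, actual,
                      bounds=DEFAULT_RANK_BOUNDS) -> list[RankGroupSummary]:
    """Rank groups + Welch tests + enrichment percentile in one pass."""
    assignment = rank_groups(predicted, bounds)
    y = np.asarray(actual, dtype=float)
    summaries = group_mean_and_test(assignment, y)
    for g, summary in enumerate(summaries):
        members = assignment.members(g)
        if members.size:
            summary.enrichment_percentile = enrichment_percentile(y[members], y)
    return summaries


# ---------------------------------------------------------------------------
# ROC / confusion
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    """Operating points (sensitivity vs 1-specificity) and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """ROC by threshold sweep over the unique scores; tie-aware trapezoid AUC."""
    from sklearn.metrics import auc as sk_auc
    from sklearn.metrics import roc_curve as sk_roc_curve

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateInput("ROC needs both classes present")
    fpr, tpr, thr = sk_roc_curve(y, s, drop_intermediate=False)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(sk_auc(fpr, tpr)))


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "accuracy": self.accuracy}


def confusion(pred_labels, true_labels) -> ConfusionMatrix:
    """Binary confusion counts and accuracy."""
    p = np.asarray(pred_labels)
    t = np.asarray(true_labels)
    if p.shape != t.shape:
        raise SchemaError("predicted and true label vectors differ in length")
    for name, v in (("predicted", p), ("true", t)):
        bad = set(np.unique(v)) - {0, 1}
        if bad:
            raise SchemaError(f"{name} labels outside {{0, 1}}: {sorted(bad)}")
    return ConfusionMatrix(
        tp=int(((p == 1) & (t == 1)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
    )


# ---------------------------------------------------------------------------
# leave-one-donor-out
# ---------------------------------------------------------------------------

@dataclass
class DonorReport:
    """Held-out evaluation of one donor's cells."""

    donor: int
    n_test: int
    r: float
    groups: list[RankGroupSummary] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"donor": self.donor, "n_test": self.n_test, "r": self.r,
                "groups": [g.to_dict() for g in self.groups]}


def leave_one_donor_out(table: pd.DataFrame, model: str = "linear",
                        seed: int = 0, fractions=(0.8, 0.2, 0.0),
                        bounds=DEFAULT_RANK_BOUNDS,
                        min_cells: int = 3,
                        forward: bool = True) -> list[DonorReport]:
    """Per-donor held-out testing.

    For each donor, a model is fitted on the remaining donors (split
    0.8/0.2 into train/validation) and evaluated on the held-out donor:
    Pearson r between actual and predicted Ln(DFI), plus rank-group
    summaries.  Donors with fewer than ``min_cells`` cells are skipped
    with a warning.  ``model`` is ``"linear"`` (forward-selected
    centered-interaction OLS) or ``"nn"``.
    """
    from .modeling import (NNConfig, candidate_terms, centers_from_table,
                           fit_linear, fit_nn, forward_select, split_data)

    if model not in ("linear", "nn"):
        raise ConfigurationError(f"unknown model kind {model!r}")
    donors = sorted(pd.unique(table["donor"]))
    if len(donors) < 2:
        raise ConfigurationError("leave-one-donor-out needs at least 2 donors")
    reports = []
    for i, donor in enumerate(donors):
        held = table[table["donor"] == donor]
        if len(held) < min_cells:
            logger.warning("donor %s has %d < %d cells; skipped", donor,
                           len(held), min_cells)
            continue
        rest = table[table["donor"] != donor].reset_index(drop=True)
        donor_seed = (seed * 1009 + 7 * i + 1) % (2 ** 31)
        split = split_data(rest, fractions, seed=donor_seed)
        if model == "linear":
            train = rest[split.train]
            centers = centers_from_table(train)
            if forward:
                spec = forward_select(train, candidate_terms(centers),
                                      seed=donor_seed)
            else:
                from .synthetic import table1_model
                spec = table1_model()
            fit = fit_linear(train, type(spec)(list(spec.terms)))
            predicted = fit.predict(held)
        else:
            reg = fit_nn(rest, split, NNConfig(seed=donor_seed))
            predicted = reg.predict(held)
        actual = ln_dfi(held["DFI"].to_numpy(float))
        r = pearson_r(actual, predicted)
        groups = rank_group_report(predicted, actual, bounds)
        reports.append(DonorReport(donor=int(donor), n_test=len(held), r=r,
                                   groups=groups))
    return reports
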