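"""Predictive models linking sperm morphology to DNA fragmentation.

Three model families are implemented on per-cell feature tables with the
six morphological predictors (head circularity ``C``, head width ``HW``,
head length ``L``, midpiece width ``MW``, vacuole area ``VA``, acrosome
area ``AA``) and response Ln(DFI):

* ordinary least squares on an intercept, (uncentered) main effects, and
  centered two-factor interaction / quadratic terms, with standard errors,
  t ratios, two-sided P values and variance inflation factors per term,
  and greedy forward term selection driven by k-fold cross-validated R^2;
* a single-hidden-layer feed-forward network (tanh hidden units, linear
  output) trained full-batch with a Levenberg-Marquardt optimizer and
  validation-based early stopping;
* logistic classification of cells into low/high Ln(DFI) rank categories.

Interaction and quadratic terms carry the centering constants used at fit
time, so a fitted :class:`LinearModelSpec` is self-contained and can be
evaluated on any table with the same columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .dfi import ln_dfi
from .errors import (
    ClassBalanceError,
    ConfigurationError,
    RankError,
    SchemaError,
    TrainingError,
)

logger = logging.getLogger(__name__)

#: Morphological predictors, in canonical column order.
FEATURES: tuple[str, ...] = ("C", "HW", "L", "MW", "VA", "AA")

SPLIT_LABELS = ("train", "validation", "test")


# ---------------------------------------------------------------------------
# Term structure
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(x, "g")


@dataclass(frozen=True)
class ModelTerm:
    """One column of the design matrix.

    ``kind`` is one of ``intercept``, ``main``, ``interaction``,
    ``quadratic``.  Main effects are evaluated on the raw feature;
    interaction and quadratic terms are products of *centered* features and
    carry their centering constants (same units as the feature).
    """

    kind: str
    features: tuple[str, ...] = ()
    centers: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("intercept", "main", "interaction", "quadratic"):
            raise ConfigurationError(f"unknown term kind {self.kind!r}")
        expected = {"intercept": 0, "main": 1, "interaction": 2, "quadratic": 2}[self.kind]
        if len(self.features) != expected:
            raise ConfigurationError(
                f"{self.kind} term needs {expected} feature(s), got {self.features!r}"
            )
        if self.kind in ("interaction", "quadratic") and len(self.centers) != 2:
            raise ConfigurationError("interaction/quadratic terms need two centers")
        if self.kind == "quadratic" and self.features[0] != self.features[1]:
            raise ConfigurationError("quadratic term must repeat one feature")

    @property
    def name(self) -> str:
        if self.kind == "intercept":
            return "Intercept"
        if self.kind == "main":
            return self.features[0]
        parts = [f"({f}-{_fmt(c)})" for f, c in zip(self.features, self.centers)]
        return "*".join(parts)

    def column(self, table: pd.DataFrame) -> np.ndarray:
        """Evaluate this term on every row of ``table``."""
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise SchemaError(f"table is missing feature column(s): {missing}")
        n = len(table)
        if self.kind == "intercept":
            return np.ones(n)
        if self.kind == "main":
            return table[self.features[0]].to_numpy(float)
        col = np.ones(n)
        for f, c in zip(self.features, self.centers):
            col = col * (table[f].to_numpy(float) - c)
        return col


def intercept_term() -> ModelTerm:
    return ModelTerm("intercept")


def main_term(feature: str) -> ModelTerm:
    return ModelTerm("main", (feature,))


def product_term(f1: str, c1: float, f2: str, c2: float) -> ModelTerm:
    kind = "quadratic" if f1 == f2 else "interaction"
    return ModelTerm(kind, (f1, f2), (float(c1), float(c2)))


@dataclass
class LinearModelSpec:
    """An ordered list of terms, optionally with fitted coefficients."""

    terms: list[ModelTerm]
    estimates: np.ndarray | None = None
    response_name: str = "Ln(DFI)"

    def __post_init__(self) -> None:
        n_int = sum(t.kind == "intercept" for t in self.terms)
        if n_int != 1:
            raise ConfigurationError(f"spec must contain exactly one intercept, got {n_int}")
        names = self.term_names
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate terms in model spec")
        if self.estimates is not None:
            self.estimates = np.asarray(self.estimates, dtype=float)
            if self.estimates.shape != (len(self.terms),):
                raise ConfigurationError("estimates length must match number of terms")

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def design(self, table: pd.DataFrame) -> np.ndarray:
        return np.column_stack([t.column(table) for t in self.terms])

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        if self.estimates is None:
            raise ConfigurationError("model spec has no estimates; fit it first")
        return self.design(table) @ self.estimates

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "terms": [
                {"kind": t.kind, "features": list(t.features), "centers": list(t.centers)}
                for t in self.terms
            ],
            "estimates": None if self.estimates is None else self.estimates.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModelSpec":
        terms = [
            ModelTerm(t["kind"], tuple(t["features"]), tuple(t["centers"]))
            for t in d["terms"]
        ]
        est = d.get("estimates")
        return cls(terms, None if est is None else np.asarray(est, float),
                   d.get("response", "Ln(DFI)"))


def build_design_matrix(table: pd.DataFrame, spec: LinearModelSpec) -> np.ndarray:
    """Design matrix with one column per term of ``spec`` (spec's centers)."""
    return spec.design(table)


def centers_from_table(table: pd.DataFrame,
                       features: Sequence[str] = FEATURES) -> dict[str, float]:
    """Per-feature centering constants: the sample means of ``table``."""
    return {f: float(table[f].mean()) for f in features}


def candidate_terms(centers: Mapping[str, float],
                    features: Sequence[str] = FEATURES) -> list[ModelTerm]:
    """Full candidate set: intercept, main effects, and all products of two
    centered factors (including squares).

    For six features this is 1 + 6 + 21 = 28 terms.
    """
    terms: list[ModelTerm] = [intercept_term()]
    terms += [main_term(f) for f in features]
    for f1, f2 in combinations_with_replacement(features, 2):
        terms.append(product_term(f1, centers[f1], f2, centers[f2]))
    return terms


# ---------------------------------------------------------------------------
# Data splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """Per-record train/validation/test labels from a seeded shuffle."""

    labels: np.ndarray
    seed: int
    fractions: tuple[float, float, float]

    @property
    def train(self) -> np.ndarray:
        return self.labels == "train"

    @property
    def validation(self) -> np.ndarray:
        return self.labels == "validation"

    @property
    def test(self) -> np.ndarray:
        return self.labels == "test"

    def counts(self) -> dict[str, int]:
        return {name: int((self.labels == name).sum()) for name in SPLIT_LABELS}


def split_data(table_or_n, fractions: Sequence[float] = (0.65, 0.10, 0.25),
               seed: int = 0) -> SplitAssignment:
    """Randomly partition records into train/validation/test groups.

    Group sizes are ``floor(n * f)``; leftover records are assigned to
    train first, then validation, then test.  The shuffle is seeded and
    deterministic.
    """
    n = table_or_n if isinstance(table_or_n, (int, np.integer)) else len(table_or_n)
    fracs = tuple(float(f) for f in fractions)
    if len(fracs) != 3:
        raise ConfigurationError("fractions must be a (train, validation, test) triple")
    if any(f < 0 for f in fracs):
        raise ConfigurationError(f"fractions must be nonnegative, got {fracs}")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1, got {sum(fracs)}")
    sizes = [int(np.floor(n * f)) for f in fracs]
    leftover = n - sum(sizes)
    for i in range(leftover):
        sizes[i % 3] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype="<U10")
    start = 0
    for name, size in zip(SPLIT_LABELS, sizes):
        labels[perm[start:start + size]] = name
        start += size
    return SplitAssignment(labels=labels, seed=seed, fractions=fracs)


# ---------------------------------------------------------------------------
# Least squares with diagnostics
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """OLS fit of a :class:`LinearModelSpec` with per-term diagnostics."""

    spec: LinearModelSpec
    std_errors: np.ndarray
    t_ratios: np.ndarray
    p_values: np.ndarray
    vifs: np.ndarray
    n: int
    dof: int
    r_squared: float
    residual_sd: float
    response_name: str = "Ln(DFI)"

    @property
    def estimates(self) -> np.ndarray:
        return self.spec.estimates

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.spec.predict(table)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "std_errors": self.std_errors.tolist(),
            "t_ratios": self.t_ratios.tolist(),
            "p_values": self.p_values.tolist(),
            "vifs": self.vifs.tolist(),
            "n": self.n,
            "dof": self.dof,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "response": self.response_name,
        }


def response_vector(table: pd.DataFrame, response=None) -> np.ndarray:
    """Ln(DFI) response: natural log of the (clipped) DFI column."""
    if response is not None:
        return np.asarray(response, dtype=float)
    if "DFI" not in table.columns:
        raise SchemaError("table has no DFI column and no explicit response was given")
    return ln_dfi(table["DFI"].to_numpy(float))


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0.0:
        raise RankError(f"design matrix is identically zero; terms: {list(names)}")
    tol = diag[0] * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise RankError(f"rank-deficient design; collinear term(s): {bad}")


def fit_linear(table: pd.DataFrame, spec: LinearModelSpec,
               response=None) -> LinearFit:
    """Ordinary least squares with SEs, t ratios, P values and VIFs.

    Standard errors use the unbiased residual-variance estimator on
    ``n - p`` degrees of freedom; P values are two-sided on the t
    distribution.  VIF of term j is ``1 / (1 - R^2_j)`` from regressing
    column j on the other non-intercept columns (plus intercept).
    """
    X = spec.design(table)
    y = response_vector(table, response)
    n, p = X.shape
    if n <= p:
        raise ConfigurationError(f"need n > number of terms ({n} rows, {p} terms)")
    _check_rank(X, spec.term_names)

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - p
    s2 = rss / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                     np.where(beta == 0, 0.0, np.sign(beta) * np.inf))
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)

    is_int = np.array([term.kind == "intercept" for term in spec.terms])
    vifs = np.full(p, np.nan)
    others_idx = np.flatnonzero(~is_int)
    int_idx = np.flatnonzero(is_int)
    for j in others_idx:
        rest = [k for k in others_idx if k != j]
        Z = X[:, np.concatenate([int_idx, rest])] if rest else X[:, int_idx]
        xj = X[:, j]
        g, _, _, _ = np.linalg.lstsq(Z, xj, rcond=None)
        rj = xj - Z @ g
        tss_j = float(((xj - xj.mean()) ** 2).sum())
        if tss_j <= 0:
            vifs[j] = np.inf
            continue
        r2_j = 1.0 - float(rj @ rj) / tss_j
        vifs[j] = np.inf if r2_j >= 1.0 else 1.0 / (1.0 - r2_j)

    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    fitted_spec = LinearModelSpec(list(spec.terms), beta, spec.response_name)
    return LinearFit(fitted_spec, se, t, pvals, vifs, n, dof, r2, float(np.sqrt(s2)),
                     spec.response_name)


# ---------------------------------------------------------------------------
# Forward selection
# ---------------------------------------------------------------------------

def _cv_r2(cols: np.ndarray, y: np.ndarray, idx: list[int],
           fold_ids: np.ndarray, folds: int) -> float:
    """Fold-averaged out-of-fold R^2 for the model using columns ``idx``."""
    scores = []
    X = cols[:, idx]
    for k in range(folds):
        te = fold_ids == k
        tr = ~te
        beta, _, _, _ = np.linalg.lstsq(X[tr], y[tr], rcond=None)
        pred = X[te] @ beta
        resid = y[te] - pred
        tss = float(((y[te] - y[te].mean()) ** 2).sum())
        if tss <= 0:
            scores.append(0.0)
        else:
            scores.append(1.0 - float(resid @ resid) / tss)
    return float(np.mean(scores))


def forward_select(table: pd.DataFrame, candidates: Sequence[ModelTerm],
                   folds: int = 5, seed: int = 0,
                   min_improvement: float | None = None,
                   response=None) -> LinearModelSpec:
    """Greedy forward term selection by cross-validated R^2.

    Starting from the intercept, the term giving the largest fold-averaged
    CV R^2 gain is added at each step; selection stops when no candidate
    improves CV R^2 by more than ``min_improvement``.  The default
    threshold, ``0.25 / sqrt(n)``, sits at the upper tail of the maximum
    spurious gain observed when the response is pure noise (the best of
    ~27 irrelevant candidates fluctuates above zero, so a zero threshold
    would admit noise terms); pass ``0.0`` for the strict
    any-improvement rule.  Ties are broken by candidate order and fold
    assignment is seeded, so the result is deterministic given ``seed``
    and the candidate order.
    """
    if not candidates:
        raise ConfigurationError("candidate term list is empty")
    cand = list(candidates)
    if not any(t.kind == "intercept" for t in cand):
        cand = [intercept_term()] + cand
    y = response_vector(table, response)
    n = len(y)
    if min_improvement is None:
        min_improvement = 0.25 / np.sqrt(n)
    cols = np.column_stack([t.column(table) for t in cand])
    rng = np.random.default_rng(seed)
    fold_ids = np.empty(n, dtype=int)
    fold_ids[rng.permutation(n)] = np.arange(n) % folds

    selected = [next(i for i, t in enumerate(cand) if t.kind == "intercept")]
    remaining = [i for i in range(len(cand)) if i not in selected]
    best = _cv_r2(cols, y, selected, fold_ids, folds)
    while remaining:
        gains = np.array([
            _cv_r2(cols, y, selected + [j], fold_ids, folds) - best
            for j in remaining
        ])
        k = int(np.argmax(gains))
        if gains[k] <= min_improvement:
            break
        best += float(gains[k])
        selected.append(remaining.pop(k))
        logger.debug("forward_select: added %s (cv R^2 = %.4f)",
                     cand[selected[-1]].name, best)
    # report terms in candidate order for stability
    selected_sorted = sorted(selected)
    return LinearModelSpec([cand[i] for i in selected_sorted])


# ---------------------------------------------------------------------------
# Neural network (Levenberg-Marquardt, early stopping)
# ---------------------------------------------------------------------------

@dataclass
class NNConfig:
    """One-hidden-layer network configuration (tanh hidden, linear output)."""

    hidden_nodes: int = 20
    activation: str = "tanh"
    max_validation_failures: int = 20
    max_epochs: int = 300
    seed: int = 0
    lambda_init: float = 1e-3

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1:
            raise ConfigurationError("hidden_nodes must be >= 1")
        if self.activation != "tanh":
            raise ConfigurationError("only tanh hidden activation is supported")


class NeuralRegressor:
    """Fitted feed-forward regressor (weights at best validation loss)."""

    def __init__(self, theta: np.ndarray, n_inputs: int, hidden: int,
                 features: Sequence[str], x_mean: np.ndarray, x_sd: np.ndarray,
                 y_mean: float, y_sd: float, degenerate_response: bool,
                 history: dict, n_epochs: int):
        self.theta = theta
        self.n_inputs = n_inputs
        self.hidden = hidden
        self.features = list(features)
        self.x_mean = x_mean
        self.x_sd = x_sd
        self.y_mean = y_mean
        self.y_sd = y_sd
        self.degenerate_response = degenerate_response
        self.history = history
        self.n_epochs = n_epochs

    def _unpack(self):
        d, h = self.n_inputs, self.hidden
        t = self.theta
        W1 = t[: h * d].reshape(h, d)
        b1 = t[h * d: h * d + h]
        W2 = t[h * d + h: h * d + 2 * h]
        b2 = t[-1]
        return W1, b1, W2, b2

    def predict(self, table) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            X = table[self.features].to_numpy(float)
        else:
            X = np.asarray(table, dtype=float)
        Xs = (X - self.x_mean) / self.x_sd
        W1, b1, W2, b2 = self._unpack()
        a = np.tanh(Xs @ W1.T + b1)
        ys = a @ W2 + b2
        return ys * self.y_sd + self.y_mean


def _nn_forward(theta: np.ndarray, X: np.ndarray, d: int, h: int):
    W1 = theta[: h * d].reshape(h, d)
    b1 = theta[h * d: h * d + h]
    W2 = theta[h * d + h: h * d + 2 * h]
    b2 = theta[-1]
    a = np.tanh(X @ W1.T + b1)
    return a, a @ W2 + b2, W2


def fit_nn(table: pd.DataFrame, split: SplitAssignment, config: NNConfig,
           features: Sequence[str] = FEATURES, response=None) -> NeuralRegressor:
    """Train the network full-batch with Levenberg-Marquardt updates.

    Inputs (and the response) are standardized on training statistics.  One
    epoch is one accepted full-batch LM step; after each epoch the
    validation MSE is evaluated, and training stops once it has failed to
    improve for ``config.max_validation_failures`` consecutive epochs.  The
    returned weights are those with the best validation loss seen.
    """
    y_all = response_vector(table, response)
    X_all = table[list(features)].to_numpy(float)
    tr, va = split.train, split.validation
    if tr.sum() == 0 or va.sum() == 0:
        raise ConfigurationError("training and validation sets must be nonempty")
    Xtr, ytr = X_all[tr], y_all[tr]
    Xva, yva = X_all[va], y_all[va]

    x_mean = Xtr.mean(axis=0)
    x_sd = Xtr.std(axis=0)
    x_sd[x_sd == 0] = 1.0
    y_mean = float(ytr.mean())
    y_sd = float(ytr.std())
    if y_sd == 0.0:
        # constant response: nothing to learn, the correlation is undefined
        logger.warning("fit_nn: constant training response; correlation undefined")
        d, h = Xtr.shape[1], config.hidden_nodes
        theta = np.zeros(h * d + 2 * h + 1)
        return NeuralRegressor(theta, d, h, features, x_mean, x_sd, y_mean,
                               1.0, True, {"train": [], "validation": []}, 0)

    Xs = (Xtr - x_mean) / x_sd
    ys = (ytr - y_mean) / y_sd
    Xvs = (Xva - x_mean) / x_sd
    yvs = (yva - y_mean) / y_sd

    d, h = Xs.shape[1], config.hidden_nodes
    n_params = h * d + 2 * h + 1
    rng = np.random.default_rng(config.seed)
    theta = rng.normal(0.0, 1.0 / np.sqrt(d + 1), n_params)

    def loss_of(t: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
        _, pred, _ = _nn_forward(t, X, d, h)
        return float(np.mean((pred - y) ** 2))

    lam = config.lambda_init
    train_loss = loss_of(theta, Xs, ys)
    best_theta = theta.copy()
    best_val = loss_of(theta, Xvs, yvs)
    failures = 0
    history = {"train": [train_loss], "validation": [best_val]}
    n = Xs.shape[0]
    epoch = 0
    while epoch < config.max_epochs:
        a, pred, W2 = _nn_forward(theta, Xs, d, h)
        r = pred - ys
        g = (1.0 - a ** 2) * W2            # n x h
        Jw1 = (g[:, :, None] * Xs[:, None, :]).reshape(n, h * d)
        J = np.concatenate([Jw1, g, a, np.ones((n, 1))], axis=1)
        JtJ = J.T @ J
        Jtr = J.T @ r
        improved = False
        for _ in range(30):
            A = JtJ + lam * np.diag(np.diag(JtJ) + 1e-12)
            try:
                delta = np.linalg.solve(A, -Jtr)
            except np.linalg.LinAlgError:
                delta, _, _, _ = np.linalg.lstsq(A, -Jtr, rcond=None)
            cand = theta + delta
            cand_loss = loss_of(cand, Xs, ys)
            if not np.isfinite(cand_loss):
                raise TrainingError("non-finite training loss")
            if cand_loss < train_loss:
                theta = cand
                train_loss = cand_loss
                lam = max(lam / 10.0, 1e-12)
                improved = True
                break
            lam *= 10.0
            if lam > 1e12:
                break
        if not improved:
            break
        epoch += 1
        val_loss = loss_of(theta, Xvs, yvs)
        history["train"].append(train_loss)
        history["validation"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_theta = theta.copy()
            failures = 0
        else:
            failures += 1
            if failures >= config.max_validation_failures:
                break

    return NeuralRegressor(best_theta, d, h, features, x_mean, x_sd,
                           y_mean, y_sd, False, history, epoch)


# ---------------------------------------------------------------------------
# Logistic classification of Ln(DFI) rank categories
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Maximum-likelihood logistic classifier of high-DFI cells.

    The positive class is "Ln(DFI) above the ``threshold_percentile``-th
    percentile of the *training* distribution" (relatively fragmented DNA,
    i.e. the bad category).  ``cutoff`` is the probability decision
    threshold for predicted labels.
    """

    intercept: float
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    threshold_percentile: float
    threshold_value: float
    cutoff: float = 0.5
    features: tuple[str, ...] = FEATURES

    def _linpred(self, table: pd.DataFrame) -> np.ndarray:
        X = table[list(self.features)].to_numpy(float)
        beta = np.array([self.coefficients[f] for f in self.features])
        return self.intercept + X @ beta

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self._linpred(table)))

    def predict_label(self, table: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(table) > self.cutoff).astype(int)

    def true_labels(self, table: pd.DataFrame, response=None) -> np.ndarray:
        """Rank labels induced by the training threshold on Ln(DFI)."""
        ln = response_vector(table, response)
        return (ln > self.threshold_value).astype(int)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "threshold_percentile": self.threshold_percentile,
            "threshold_value": self.threshold_value,
            "cutoff": self.cutoff,
            "features": list(self.features),
        }


def fit_logistic(table: pd.DataFrame, split: SplitAssignment,
                 threshold_percentile: float = 80.0, seed: int = 0,
                 features: Sequence[str] = FEATURES, cutoff: float = 0.5,
                 response=None) -> LogisticFit:
    """Fit the rank-category classifier on the six morphology features.

    The percentile threshold is computed on the training rows only (no
    leakage of validation/test ranks); the unpenalized fit itself is
    deterministic, ``seed`` only seeds the solver's internals.
    """
    from sklearn.linear_model import LogisticRegression

    ln = response_vector(table, response)
    thr = float(np.percentile(ln[split.train], threshold_percentile))
    labels = (ln > thr).astype(int)
    ytr = labels[split.train]
    if len(np.unique(ytr)) < 2:
        raise ClassBalanceError(
            f"training set has a single class at percentile {threshold_percentile}"
        )
    Xtr = table.loc[split.train, list(features)].to_numpy(float)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000,
                             tol=1e-10, random_state=seed)
    clf.fit(Xtr, ytr)
    beta = np.concatenate([clf.intercept_, clf.coef_.ravel()])

    # Fisher-information standard errors at the MLE
    Xd = np.column_stack([np.ones(len(Xtr)), Xtr])
    p = 1.0 / (1.0 + np.exp(-(Xd @ beta)))
    W = p * (1.0 - p)
    cov = np.linalg.pinv(Xd.T @ (Xd * W[:, None]))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    names = list(features)
    return LogisticFit(
        intercept=float(beta[0]),
        coefficients={f: float(b) for f, b in zip(names, beta[1:])},
        std_errors={"Intercept": float(se[0]), **{f: float(s) for f, s in zip(names, se[1:])}},
        threshold_percentile=float(threshold_percentile),
        threshold_value=thr,
        cutoff=cutoff,
        features=tuple(features),
    )
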