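"""Splitting, class weighting, feature selection, logistic probes, fusion.

Estimators follow scikit-learn conventions (``fit``/``transform`` or
``predict_proba``, ``get_params``/``set_params``, trailing-underscore
fitted attributes) so they compose with sklearn pipelines and model
selection. Module-level functions are thin wrappers kept for script use.

Leakage discipline: every statistic that informs the model — feature
selection, standardization means/sds, the L1 strength grid — is computed
on the training split only and then applied frozen to validation and
test data. Splits are patient-level so no patient contributes to two
splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, EmphkitError
from .qct import QCTMarkers

SPLIT_RATIOS = (0.70, 0.15, 0.15)
SPLIT_NAMES = ("train", "val", "test")


@dataclass
class SplitAssignment:
    """Patient-level split with its audit log of ids per split."""

    assignment: dict[str, str]
    ratios: tuple[float, float, float]
    seed: int

    def ids(self, split: str) -> list[str]:
        return [p for p, s in self.assignment.items() if s == split]

    def log(self) -> dict[str, list[str]]:
        """Patient-id log per split, for leakage audits."""
        return {s: sorted(self.ids(s)) for s in SPLIT_NAMES}


@dataclass
class WeightSpec:
    """Inverse-frequency class weights: w_c = N / (2 * N_c)."""

    class_weights: dict[int, float]

    def sample_weights(self, y: np.ndarray) -> np.ndarray:
        return np.array([self.class_weights[int(c)] for c in y])


@dataclass
class SelectionResult:
    """Outcome of one feature-selection strategy."""

    method: str
    selected_indices: list[int]
    k: int
    per_feature_stats: "np.ndarray | None" = None  # columns (t, p, p_adj)

    def __post_init__(self) -> None:
        if len(set(self.selected_indices)) != len(self.selected_indices):
            raise ValueError("selected indices must be unique")


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    """Integer allocation of n items to ratios; remainders resolved by
    largest fractional part, ties in declaration (train, val, test) order."""
    exact = [n * r for r in ratios]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    rema = sorted(
        range(len(ratios)), key=lambda i: (-(exact[i] - base[i]), i)
    )
    for i in rema[:short]:
        base[i] += 1
    return base


def stratified_patient_split(
    labels: Mapping[str, int],
    ratios: tuple[float, float, float] = SPLIT_RATIOS,
    seed: int = 0,
) -> SplitAssignment:
    """Shuffle each class and allocate 70/15/15 by largest remainder.

    Per-class counts deviate from the exact ratio allocation by less
    than one patient per split.
    """
    if any(r <= 0 for r in ratios) or not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must be positive and sum to 1")
    by_class: dict[int, list[str]] = {}
    for pid, y in labels.items():
        by_class.setdefault(int(y), []).append(pid)
    if any(len(v) == 0 for v in by_class.values()) or len(by_class) < 2:
        raise DegenerateDataError("degenerate stratification: a class is empty")

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for cls in sorted(by_class):
        ids = sorted(by_class[cls])
        rng.shuffle(ids)
        counts = _largest_remainder(len(ids), ratios)
        pos = 0
        for split, cnt in zip(SPLIT_NAMES, counts):
            for pid in ids[pos : pos + cnt]:
                assignment[pid] = split
            pos += cnt
    return SplitAssignment(assignment, tuple(ratios), seed)


def inverse_frequency_weights(y: Sequence[int]) -> WeightSpec:
    """w_c = N / (2 * N_c); the weighted sample count always equals N."""
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DegenerateDataError("degenerate weighting: single-class input")
    n = y.size
    return WeightSpec({int(c): n / (2.0 * cnt) for c, cnt in zip(classes, counts)})


class TTestFDRSelector(TransformerMixin, BaseEstimator):
    """Top-k features by Welch t-test with Benjamini-Hochberg adjustment.

    Per feature: Welch two-sample t (Welch-Satterthwaite df), two-sided
    p; BH step-up across all features; rank by adjusted p, then raw p,
    then column index; keep the first ``k``. Features with zero variance
    in both classes get p = 1 and are never selected ahead of any
    informative feature.
    """

    def __init__(self, k: int = 20):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        a, b = X[y == 1], X[y == 0]
        if min(len(a), len(b)) < 2:
            raise DegenerateDataError("need >= 2 samples per class")
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = sps.ttest_ind(a, b, equal_var=False)
        degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0) & (
            a.mean(axis=0) == b.mean(axis=0)
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
        p = np.where(np.isinf(t), 0.0, p)  # zero variance, separated means
        t = np.where(np.isfinite(t), t, 0.0)
        p = np.where(np.isfinite(p), p, 1.0)
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        order = np.lexsort((np.arange(X.shape[1]), p, p_adj))
        order = order[~degenerate[order]]
        self.selected_indices_ = [int(i) for i in order[: self.k]]
        self.stats_ = np.column_stack([t, p, p_adj])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_indices_")
        return np.asarray(X)[:, self.selected_indices_]

    def result(self) -> SelectionResult:
        check_is_fitted(self, "selected_indices_")
        return SelectionResult(
            "ttest_fdr", self.selected_indices_, self.k, self.stats_
        )


class LogisticProbe(ClassifierMixin, BaseEstimator):
    """Class-weighted, standardized logistic regression probe.

    Features are standardized with training-split statistics inside
    ``fit``; coefficients are reported on the standardized scale.
    ``strength`` is the inverse regularization constant (sklearn's C):
    small values regularize hard (with L1, driving all coefficients to
    zero), large values approach the unpenalized fit.
    """

    def __init__(
        self,
        penalty: str = "l2",
        strength: float = 1.0,
        class_weights: WeightSpec | None = None,
        max_iter: int = 5000,
        tol: float = 1e-8,
    ):
        self.penalty = penalty
        self.strength = strength
        self.class_weights = class_weights
        self.max_iter = max_iter
        self.tol = tol

    def _weights(self, y) -> dict[int, float]:
        if self.class_weights is not None:
            return self.class_weights.class_weights
        return {0: 1.0, 1: 1.0}

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        self.classes_ = np.unique(y)
        self.mean_ = X.mean(axis=0) if X.shape[1] else np.zeros(0)
        sd = X.std(axis=0, ddof=0) if X.shape[1] else np.zeros(0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        Xs = (X - self.mean_) / self.sd_

        cw = self._weights(y)
        if X.shape[1] == 0:
            # Intercept-only: the weighted-likelihood stationary point is
            # the weighted prevalence, in closed form.
            w = np.array([cw[int(c)] for c in y], dtype=float)
            prev = float(w[y == 1].sum() / w.sum())
            prev = min(max(prev, 1e-12), 1 - 1e-12)
            self.coef_ = np.zeros((1, 0))
            self.intercept_ = np.array([np.log(prev / (1 - prev))])
            self.n_iter_ = np.array([0])
            return self

        est = self._base_estimator(cw)
        est.fit(Xs, y)
        if np.any(est.n_iter_ >= self.max_iter):
            raise EmphkitError(
                f"no convergence after {self.max_iter} iterations "
                f"(penalty={self.penalty}, strength={self.strength})"
            )
        self.coef_ = est.coef_
        self.intercept_ = est.intercept_
        self.n_iter_ = est.n_iter_
        return self

    def _base_estimator(self, class_weight: dict[int, float]):
        """sklearn backend; prefers the l1_ratio API (sklearn >= 1.8)."""
        common = dict(
            class_weight=class_weight, max_iter=self.max_iter, tol=self.tol
        )
        if self.penalty not in ("l1", "l2", "none"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        try:
            if self.penalty == "none":
                return LogisticRegression(
                    C=np.inf, l1_ratio=0.0, solver="lbfgs", **common
                )
            return LogisticRegression(
                C=self.strength,
                l1_ratio=1.0 if self.penalty == "l1" else 0.0,
                solver="liblinear",
                **common,
            )
        except TypeError:  # older sklearn without plain l1_ratio support
            if self.penalty == "none":
                return LogisticRegression(penalty=None, solver="lbfgs", **common)
            return LogisticRegression(
                penalty=self.penalty,
                C=self.strength,
                solver="liblinear",
                **common,
            )

    def decision_function(self, X):
        """Raw logit (pre-sigmoid) per scan."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] == 0:
            return np.full(X.shape[0], self.intercept_[0])
        Xs = (X - self.mean_) / self.sd_
        return Xs @ self.coef_[0] + self.intercept_[0]

    def predict_proba(self, X):
        from scipy.special import expit

        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)

    @property
    def coefficients(self) -> np.ndarray:
        return self.coef_[0]


class ProbeRFE(TransformerMixin, BaseEstimator):
    """Recursive feature elimination driven by an L2 logistic probe.

    Repeatedly fits the class-weighted L2 probe on standardized features
    and drops the 10% of remaining features (at least one) with the
    smallest absolute coefficients, until ``n_keep`` remain.
    """

    def __init__(
        self,
        n_keep: int = 20,
        step_frac: float = 0.10,
        strength: float = 1.0,
        class_weights: WeightSpec | None = None,
    ):
        self.n_keep = n_keep
        self.step_frac = step_frac
        self.strength = strength
        self.class_weights = class_weights

    def fit(self, X, y):
        if self.n_keep < 1:
            raise ValueError("invalid target: n_keep must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if self.n_keep > X.shape[1]:
            raise ValueError("n_keep exceeds feature dimensionality")
        remaining = list(range(X.shape[1]))
        while len(remaining) > self.n_keep:
            probe = LogisticProbe(
                penalty="l2",
                strength=self.strength,
                class_weights=self.class_weights,
            ).fit(X[:, remaining], y)
            n_drop = max(1, int(np.floor(self.step_frac * len(remaining))))
            n_drop = min(n_drop, len(remaining) - self.n_keep)
            order = np.argsort(
                np.abs(probe.coefficients), kind="stable"
            )[:n_drop]
            for i in sorted(order, reverse=True):
                del remaining[i]
        self.selected_indices_ = remaining
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_indices_")
        return np.asarray(X)[:, self.selected_indices_]

    def result(self) -> SelectionResult:
        check_is_fitted(self, "selected_indices_")
        return SelectionResult("rfe", self.selected_indices_, self.n_keep)


def ttest_fdr_select(X, y, k: int = 20) -> SelectionResult:
    return TTestFDRSelector(k=k).fit(X, y).result()


def rfe_select(
    X, y, n_keep: int, step_frac: float = 0.10,
    class_weights: WeightSpec | None = None,
) -> SelectionResult:
    return (
        ProbeRFE(n_keep=n_keep, step_frac=step_frac, class_weights=class_weights)
        .fit(X, y)
        .result()
    )


def lasso_select(
    X, y, strength: float = 1.0, class_weights: WeightSpec | None = None
) -> SelectionResult:
    """Features with nonzero coefficients in an L1 probe."""
    probe = LogisticProbe(
        penalty="l1", strength=strength, class_weights=class_weights
    ).fit(X, y)
    idx = [int(i) for i in np.flatnonzero(probe.coefficients != 0)]
    return SelectionResult("lasso", idx, k=len(idx))


def fit_logistic_probe(
    X,
    y,
    weights: WeightSpec | None = None,
    penalty: str = "l2",
    strength: float = 1.0,
) -> LogisticProbe:
    return LogisticProbe(
        penalty=penalty, strength=strength, class_weights=weights
    ).fit(X, y)


L1_STRENGTH_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


def choose_l1_strength(
    X_train, y_train, X_val, y_val,
    weights: WeightSpec | None = None,
    grid: Sequence[float] = L1_STRENGTH_GRID,
) -> tuple[float, LogisticProbe]:
    """Pick the L1 strength maximizing validation ROC-AUC over a small
    logarithmic grid; ties favour the stronger penalty (sparser model)."""
    from .evaluation import roc_auc

    best = None
    for c in grid:
        probe = LogisticProbe(penalty="l1", strength=c, class_weights=weights)
        probe.fit(X_train, y_train)
        scores = probe.decision_function(X_val)
        if np.unique(np.asarray(y_val)).size < 2:
            raise DegenerateDataError("validation split lacks a class")
        auc = roc_auc(scores, y_val)
        if best is None or auc > best[0] + 1e-12:
            best = (auc, c, probe)
    return best[1], best[2]


@dataclass
class FusionStandardizer:
    """Train-split column statistics for the 4-d fusion vector."""

    mean: np.ndarray
    sd: np.ndarray


FUSION_COLUMNS = ("logit", "laa950_pct", "perc15_hu", "tlv_l")


def fusion_matrix(
    logits: Sequence[float], markers: Sequence[QCTMarkers]
) -> np.ndarray:
    """Stack [logit, %LAA-950, Perc15, TLV] per scan, unstandardized."""
    if len(logits) != len(markers):
        raise ValueError("one logit per scan required")
    rows = []
    for logit, m in zip(logits, markers):
        row = [logit, m.laa950_pct, m.perc15_hu, m.tlv_l]
        if any(v is None or not np.isfinite(v) for v in row):
            raise EmphkitError(f"incomplete fusion row for {m.patient_id!r}")
        rows.append(row)
    return np.asarray(rows, dtype=float)


def build_fusion_features(
    logits: Sequence[float],
    markers: Sequence[QCTMarkers],
    train_mask: Sequence[bool],
    standardizer: FusionStandardizer | None = None,
) -> tuple[np.ndarray, FusionStandardizer]:
    """Standardize fusion columns with training-split statistics only.

    ``train_mask`` marks the rows belonging to the training split; other
    rows are transformed with the frozen train mean/sd, never their own.
    """
    X = fusion_matrix(logits, markers)
    if standardizer is None:
        tr = np.asarray(train_mask, dtype=bool)
        if not tr.any():
            raise ValueError("train_mask selects no rows")
        mean = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=0)
        standardizer = FusionStandardizer(mean, np.where(sd > 0, sd, 1.0))
    return (X - standardizer.mean) / standardizer.sd, standardizer
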