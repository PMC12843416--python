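"""Classification metrics, percentile-bootstrap CIs and embedding
diagnostics, all implemented from their definitions.

* ROC-AUC is the Mann-Whitney rank statistic: the fraction of
  (positive, negative) score pairs ordered correctly, ties counted 1/2.
* Average precision is the step-wise sum sum_k (R_k - R_{k-1}) P_k over
  descending unique score thresholds, ties grouped — not trapezoidal.
* Confidence intervals are percentile bootstrap at the patient level:
  resample patients with replacement B times, recompute the metric,
  take the empirical 2.5/97.5 percentiles. Resamples that lack a class
  needed by the metric are redrawn (bounded), keeping exactly B values.
* Cluster separation (silhouette, Calinski-Harabasz, Davies-Bouldin)
  and PCA are spelled out from the textbook definitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import BootstrapError, DegenerateDataError


@dataclass
class ConfusionCounts:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def __str__(self) -> str:
        return f"{self.tn}/{self.fp}/{self.fn}/{self.tp}"


def confusion_at_threshold(
    probabilities, labels, threshold: float = 0.5
) -> ConfusionCounts:
    """2x2 counts with 'predict positive iff probability >= threshold'."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("misaligned inputs: scores and labels differ in length")
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tp=int(np.sum(pred & pos)),
    )


def f1_score(cm: ConfusionCounts) -> float:
    """2*TP / (2*TP + FP + FN); zero when the denominator vanishes."""
    denom = 2 * cm.tp + cm.fp + cm.fn
    return 2.0 * cm.tp / denom if denom else 0.0


def balanced_accuracy(cm: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise DegenerateDataError("undefined bACC: a class is absent")
    return 0.5 * (cm.tp / (cm.tp + cm.fn) + cm.tn / (cm.tn + cm.fp))


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + P(tie)/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise DegenerateDataError("undefined AUC: need both classes")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def average_precision(scores, labels) -> float:
    """Step-wise AP over descending unique thresholds, ties grouped."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    if n_pos == 0:
        raise DegenerateDataError("undefined AP: no positives")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    ap = 0.0
    tp = 0
    seen = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp_prev = tp
        tp += int(np.sum(y[i:j] == 1))
        seen = j
        recall_step = (tp - tp_prev) / n_pos
        precision = tp / seen
        ap += recall_step * precision
        i = j
    return float(ap)


@dataclass
class BootstrapResult:
    point: float
    low: float
    high: float
    values: np.ndarray

    def __iter__(self):
        return iter((self.point, self.low, self.high))


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    scores,
    labels,
    patient_ids: Sequence[str] | None = None,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    max_redraw_factor: int = 100,
) -> BootstrapResult:
    """Percentile-bootstrap CI of a metric, resampling patients.

    Each resample draws patients with replacement and evaluates the
    metric on their scans. Resamples on which the metric is undefined
    (e.g. a single-class draw for AUC) are redrawn; after
    ``max_redraw_factor * B`` total draws without B successes the
    bootstrap is declared degenerate.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("misaligned inputs")
    if patient_ids is None:
        groups = None  # scan-level == patient-level: resample rows directly
    else:
        uniq: dict[str, list[int]] = {}
        for i, pid in enumerate(patient_ids):
            uniq.setdefault(pid, []).append(i)
        groups = [np.array(v) for v in uniq.values()]
    n_groups = len(groups) if groups is not None else len(s)

    point = float(metric(s, y))
    rng = np.random.default_rng(seed)
    values = np.empty(B, dtype=float)
    got = 0
    draws = 0
    limit = max_redraw_factor * B
    while got < B:
        draws += 1
        if draws > limit:
            raise BootstrapError(
                "degenerate bootstrap: redraw bound exceeded "
                f"({got}/{B} valid resamples)"
            )
        pick = rng.integers(0, n_groups, n_groups)
        idx = pick if groups is None else np.concatenate(
            [groups[g] for g in pick]
        )
        try:
            values[got] = metric(s[idx], y[idx])
        except DegenerateDataError:
            continue
        got += 1
    low, high = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(point, float(low), float(high), values)


@dataclass
class EvalReport:
    """Point estimates with percentile-bootstrap CIs plus the confusion
    matrix at the decision threshold."""

    metrics: dict[str, tuple[float, float, float]]
    confusion: ConfusionCounts
    threshold: float = 0.5
    B: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (pt, lo, hi) in self.metrics.items():
            if not (lo <= pt + 1e-12 and pt - 1e-12 <= hi):
                raise ValueError(f"CI must bracket the point estimate ({name})")

    def to_json(self) -> str:
        return json.dumps(
            {
                "metrics": {
                    k: {"point": p, "ci_low": lo, "ci_high": hi}
                    for k, (p, lo, hi) in self.metrics.items()
                },
                "confusion_tn_fp_fn_tp": str(self.confusion),
                "threshold": self.threshold,
                "B": self.B,
                "alpha": self.alpha,
                "seed": self.seed,
            },
            indent=1,
        )


def evaluate_probe(
    probabilities,
    labels,
    patient_ids: Sequence[str] | None = None,
    threshold: float = 0.5,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> EvalReport:
    """Full report: ROC-AUC, PR-AUC, F1 and bACC with bootstrap CIs."""
    cm = confusion_at_threshold(probabilities, labels, threshold)

    def f1_metric(s, y):
        return f1_score(confusion_at_threshold(s, y, threshold))

    def bacc_metric(s, y):
        return balanced_accuracy(confusion_at_threshold(s, y, threshold))

    metrics = {}
    for name, fn in (
        ("roc_auc", roc_auc),
        ("pr_auc", average_precision),
        ("f1", f1_metric),
        ("bacc", bacc_metric),
    ):
        res = bootstrap_ci(
            fn, probabilities, labels, patient_ids, B=B, alpha=alpha, seed=seed
        )
        metrics[name] = (res.point, res.low, res.high)
    return EvalReport(metrics, cm, threshold, B, alpha, seed)


def cluster_separation(features, labels) -> tuple[float, float, float]:
    """Silhouette, Calinski-Harabasz and Davies-Bouldin, Euclidean.

    Textbook definitions: per-point silhouette (b - a)/max(a, b) with a
    the mean intra-cluster and b the smallest mean other-cluster
    distance (singleton clusters score 0); CH is the
    between/within-dispersion ratio scaled by (n-k)/(k-1); DB is the
    mean over clusters of the worst pairwise similarity
    (s_i + s_j)/d_ij.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateDataError("need >= 2 clusters")
    n, k = len(X), len(classes)

    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))

    sil = np.zeros(n)
    for i in range(n):
        same = (y == y[i]) & (np.arange(n) != i)
        if not same.any():
            sil[i] = 0.0
            continue
        a = dist[i, same].mean()
        b = min(dist[i, y == c].mean() for c in classes if c != y[i])
        sil[i] = (b - a) / max(a, b)
    silhouette = float(sil.mean())

    overall = X.mean(axis=0)
    centroids = {c: X[y == c].mean(axis=0) for c in classes}
    between = sum(
        np.sum(y == c) * np.sum((centroids[c] - overall) ** 2) for c in classes
    )
    within = sum(np.sum((X[y == c] - centroids[c]) ** 2) for c in classes)
    ch = float((between / (k - 1)) / (within / (n - k)))

    scatter = {
        c: np.mean(np.linalg.norm(X[y == c] - centroids[c], axis=1))
        for c in classes
    }
    db_terms = []
    for c in classes:
        worst = max(
            (scatter[c] + scatter[d])
            / np.linalg.norm(centroids[c] - centroids[d])
            for d in classes
            if d != c
        )
        db_terms.append(worst)
    db = float(np.mean(db_terms))
    return silhouette, ch, db


def pca_project(features, n_components: int = 2) -> np.ndarray:
    """Center and project onto the top principal axes (SVD).

    Component variances are non-increasing; signs are fixed by making
    each component's largest-magnitude loading positive so projections
    are deterministic.
    """
    X = np.asarray(features, dtype=float)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds min(n_samples, dim)")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    return u[:, :n_components] * s[:n_components]
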