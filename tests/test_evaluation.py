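"""Metrics from definition, percentile bootstrap, cluster diagnostics."""

import numpy as np
import pytest

import emphkit as ek
from emphkit.errors import BootstrapError, DegenerateDataError

# (tn, fp, fn, tp) -> printed F1 and balanced accuracy, validation and
# test rows for the three reported models
CONFUSIONS = [
    ((43, 8, 2, 6), 0.55, 0.797),
    ((39, 13, 2, 5), 0.40, 0.732),
    ((44, 7, 3, 5), 0.50, 0.744),
    ((42, 10, 3, 4), 0.38, 0.690),
    ((48, 3, 0, 8), 0.84, 0.971),
    ((51, 1, 1, 6), 0.86, 0.919),
]


def brute_force_auc(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_probabilities(self):
        cm = ek.confusion_at_threshold([0, 0, 1, 1], [0, 0, 1, 1])
        assert (cm.fp, cm.fn) == (0, 0)

    def test_threshold_zero_predicts_all_positive(self):
        cm = ek.confusion_at_threshold([0.0, 0.3, 0.9], [0, 1, 1], threshold=0.0)
        assert cm.tn == 0 and cm.fp == 1

    def test_counts_partition_sample(self, rng):
        p = rng.uniform(size=37)
        y = rng.integers(0, 2, 37)
        cm = ek.confusion_at_threshold(p, y)
        assert cm.n == 37

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            ek.confusion_at_threshold([0.5], [1, 0])


class TestF1AndBalancedAccuracy:
    @pytest.mark.parametrize("counts, f1, bacc", CONFUSIONS)
    def test_reported_confusions(self, counts, f1, bacc):
        cm = ek.ConfusionCounts(*counts)
        assert round(ek.f1_score(cm), 2) == f1
        assert round(ek.balanced_accuracy(cm), 3) == bacc

    def test_perfect_classifier(self):
        cm = ek.ConfusionCounts(50, 0, 0, 10)
        assert ek.f1_score(cm) == 1.0
        assert ek.balanced_accuracy(cm) == 1.0

    def test_f1_zero_denominator(self):
        assert ek.f1_score(ek.ConfusionCounts(10, 0, 0, 0)) == 0.0

    def test_chance_level_bacc(self):
        cm = ek.ConfusionCounts(5, 5, 5, 5)
        assert ek.balanced_accuracy(cm) == 0.5

    def test_bacc_undefined_without_both_classes(self):
        with pytest.raises(DegenerateDataError, match="undefined bACC"):
            ek.balanced_accuracy(ek.ConfusionCounts(10, 2, 0, 0))


class TestRocAuc:
    def test_separated_and_tied_extremes(self):
        assert ek.roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert ek.roc_auc([1, 1, 1, 1], [0, 0, 1, 1]) == 0.5

    def test_hand_example(self):
        assert ek.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
            assert ek.roc_auc(s, y) == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        assert ek.roc_auc(s, y) == pytest.approx(ek.roc_auc(np.exp(s), y))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError, match="undefined AUC"):
            ek.roc_auc([0.1, 0.9], [1, 1])


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert ek.average_precision([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_single_positive_at_rank_two(self):
        assert ek.average_precision([0.9, 0.1], [0, 1]) == pytest.approx(0.5)

    def test_all_positive(self):
        assert ek.average_precision([0.2, 0.9], [1, 1]) == 1.0

    def test_ties_grouped(self):
        # one threshold covers both tied scores: P = 1/2 at R = 1
        assert ek.average_precision([0.5, 0.5], [1, 0]) == pytest.approx(0.5)

    def test_matches_sklearn_on_random_instances(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(100):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, n)
            if y.sum() == 0:
                y[0] = 1
            s = np.round(rng.uniform(size=n), 1)
            assert ek.average_precision(s, y) == pytest.approx(
                average_precision_score(y, s), abs=1e-12
            )


class TestBootstrap:
    def test_exactly_b_values_and_zero_width_for_constant(self, rng):
        y = rng.integers(0, 2, 30)
        res = ek.bootstrap_ci(lambda s, t: 0.42, rng.uniform(size=30), y, B=1000, seed=1)
        assert len(res.values) == 1000
        assert res.low == res.high == 0.42

    def test_seed_reproducibility(self, rng):
        s = rng.uniform(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        a = ek.bootstrap_ci(ek.roc_auc, s, y, B=200, seed=9)
        b = ek.bootstrap_ci(ek.roc_auc, s, y, B=200, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_patient_grouping_keeps_scans_together(self):
        # two scans per patient; metric counts distinct patients drawn
        pids = [f"P{i // 2}" for i in range(20)]
        s = np.arange(20.0)
        y = np.tile([0, 1], 10)

        def pairs_intact(scores, labels):
            return 1.0 if len(scores) == 20 else 0.0

        res = ek.bootstrap_ci(pairs_intact, s, y, patient_ids=pids, B=50, seed=0)
        assert np.all(res.values == 1.0)

    def test_degenerate_resamples_redrawn_then_bounded(self):
        # two patients, one per class: half of all resamples are
        # single-class, so AUC needs redraws; a tiny budget must trip
        with pytest.raises(BootstrapError, match="degenerate bootstrap"):
            ek.bootstrap_ci(
                ek.roc_auc, [0.1, 0.9], [0, 1], B=50, seed=0, max_redraw_factor=1
            )
        res = ek.bootstrap_ci(ek.roc_auc, [0.1, 0.9], [0, 1], B=50, seed=0)
        assert len(res.values) == 50  # generous budget: exactly B values

    def test_mean_coverage_of_percentile_interval(self):
        """95% percentile CI for the mean of Normal(0,1), n = 50: the
        empirical coverage of 0 over 500 replications sits in [92, 98]%."""
        outer = np.random.default_rng(2024)
        covered = 0
        reps = 500
        for i in range(reps):
            x = outer.normal(0.0, 1.0, 50)
            res = ek.bootstrap_ci(
                lambda s, y: float(np.mean(s)), x, np.zeros(50, dtype=int),
                B=1000, seed=i,
            )
            covered += res.low <= 0.0 <= res.high
        assert 0.92 <= covered / reps <= 0.98


class TestEvalReport:
    def test_report_brackets_and_serializes(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        p = np.clip(y * 0.6 + rng.uniform(0, 0.4, 60), 0, 1)
        report = ek.evaluate_probe(p, y, B=200, seed=4)
        for name, (pt, lo, hi) in report.metrics.items():
            assert lo <= pt + 1e-12 and pt - 1e-12 <= hi
        parsed = __import__("json").loads(report.to_json())
        assert parsed["confusion_tn_fp_fn_tp"].count("/") == 3
        assert parsed["B"] == 200


class TestClusterSeparation:
    def test_tight_distant_clusters(self, rng):
        a = rng.normal(0, 0.01, (30, 4))
        b = rng.normal(10, 0.01, (30, 4))
        X = np.vstack([a, b])
        y = np.repeat([0, 1], 30)
        sil, ch, db = ek.cluster_separation(X, y)
        assert sil > 0.9 and ch > 1e4 and db < 0.1

    def test_same_distribution_gives_near_zero_silhouette(self):
        rng = np.random.default_rng(77)
        X = rng.normal(size=(200, 5))
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        sil, _, _ = ek.cluster_separation(X, y)
        assert abs(sil) < 0.1

    def test_matches_sklearn_definitions(self, rng):
        from sklearn.metrics import (
            calinski_harabasz_score,
            davies_bouldin_score,
            silhouette_score,
        )

        X = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        X[y == 1] += 1.5
        sil, ch, db = ek.cluster_separation(X, y)
        assert sil == pytest.approx(silhouette_score(X, y), abs=1e-9)
        assert ch == pytest.approx(calinski_harabasz_score(X, y), abs=1e-6)
        assert db == pytest.approx(davies_bouldin_score(X, y), abs=1e-9)

    def test_six_point_hand_instance(self):
        """All three indices recomputed by brute-force loops over the
        textbook definitions on a 6-point instance."""
        X = np.array([[0.0, 0], [1, 0], [0, 1], [10, 10], [11, 10], [10, 11]])
        y = np.array([0, 0, 0, 1, 1, 1])
        sil, ch, db = ek.cluster_separation(X, y)

        d = lambda i, j: float(np.linalg.norm(X[i] - X[j]))
        sils = []
        for i in range(6):
            own = [d(i, j) for j in range(6) if y[j] == y[i] and j != i]
            other = [d(i, j) for j in range(6) if y[j] != y[i]]
            a, b = np.mean(own), np.mean(other)
            sils.append((b - a) / max(a, b))
        assert sil == pytest.approx(np.mean(sils), abs=1e-12)

        mu = X.mean(0)
        c0, c1 = X[:3].mean(0), X[3:].mean(0)
        between = 3 * np.sum((c0 - mu) ** 2) + 3 * np.sum((c1 - mu) ** 2)
        within = np.sum((X[:3] - c0) ** 2) + np.sum((X[3:] - c1) ** 2)
        assert ch == pytest.approx((between / 1) / (within / 4), rel=1e-12)

        s0 = np.mean(np.linalg.norm(X[:3] - c0, axis=1))
        s1 = np.mean(np.linalg.norm(X[3:] - c1, axis=1))
        expected_db = (s0 + s1) / np.linalg.norm(c0 - c1)
        assert db == pytest.approx(expected_db, abs=1e-12)


class TestPca:
    def test_projection_centered_and_ordered(self, rng):
        X = rng.normal(size=(50, 6)) * np.array([5, 3, 1, 1, 1, 1])
        coords = ek.pca_project(X, 2)
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-9)
        assert coords[:, 0].var() >= coords[:, 1].var()

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(20, 5))
        Xc = X - X.mean(axis=0)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        assert np.allclose(u * s @ vt, Xc, atol=1e-9)
        coords = ek.pca_project(X, 5)
        # projecting onto all components preserves pairwise distances
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(coords), pdist(Xc), atol=1e-8)

    def test_component_bound_rejected(self, rng):
        with pytest.raises(ValueError):
            ek.pca_project(rng.normal(size=(4, 3)), 5)
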