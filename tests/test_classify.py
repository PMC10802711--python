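"""Threshold model, ROC/Youden, cross-validation and the ML comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

import gapfseq as g
from gapfseq.classify import ML_FEATURE_CHROMS, sample_scores


def mann_whitney_auc(scores, y):
    """Pairwise rank-statistic oracle: ties count 1/2."""
    t, n = scores[y == 1], scores[y == 0]
    return sum(
        1.0 if a > b else 0.5 if a == b else 0.0 for a in t for b in n
    ) / (len(t) * len(n))


score_sets = st.tuples(
    st.lists(st.integers(0, 12), min_size=1, max_size=8),
    st.lists(st.integers(0, 12), min_size=1, max_size=8),
)


class TestScoresAndCalls:
    def test_score_is_max_chromosome_count(self):
        X = np.array([[135, 121] + [60] * 21])
        assert sample_scores(X)[0] == 135

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            sample_scores(np.empty((1, 0)))

    @pytest.mark.parametrize("score,threshold,call", [(135, 100, True), (99, 100, False),
                                                      (100, 100, True)])
    def test_boundary_convention(self, score, threshold, call):
        assert g.classify_threshold([score], threshold)[0] == call

    def test_strict_gt_flag(self):
        assert not g.classify_threshold([100], 100, strict_gt=True)[0]

    @given(st.lists(st.integers(0, 400), min_size=1, max_size=20), st.integers(0, 400))
    def test_monotone_in_threshold(self, scores, t):
        lo = g.classify_threshold(scores, t)
        hi = g.classify_threshold(scores, t + 1)
        assert not np.any(hi & ~lo)  # raising threshold never creates a positive

    def test_all_positive_and_all_negative_endpoints(self):
        scores = np.array([70, 200, 915, 130])
        assert g.classify_threshold(scores, 0).all()
        assert g.classify_threshold(scores, int(scores.min())).all()
        assert not g.classify_threshold(scores, int(scores.max()) + 1).any()


class TestROC:
    @given(score_sets)
    def test_trapezoidal_auc_equals_mann_whitney(self, sets):
        t, n = sets
        scores = np.array(t + n)
        y = np.array([1] * len(t) + [0] * len(n))
        r = g.roc_from_scores(scores, y)
        assert r.auc == pytest.approx(mann_whitney_auc(scores, y), abs=1e-12)

    @given(score_sets)
    def test_label_inversion_maps_auc_to_complement(self, sets):
        t, n = sets
        scores = np.array(t + n)
        y = np.array([1] * len(t) + [0] * len(n))
        assert g.roc_from_scores(scores, 1 - y).auc == pytest.approx(
            1 - g.roc_from_scores(scores, y).auc, abs=1e-12
        )

    def test_perfect_separation(self):
        r = g.roc_from_scores(np.array([150, 120, 110, 40, 60, 90]),
                              np.array([1, 1, 1, 0, 0, 0]))
        assert r.auc == 1.0 and r.youden_j == 1.0
        assert 90 < r.optimal_threshold <= 110

    def test_identical_score_multisets_auc_half(self):
        scores = np.array([5, 7, 9, 5, 7, 9])
        y = np.array([1, 1, 1, 0, 0, 0])
        assert g.roc_from_scores(scores, y).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            g.roc_from_scores(np.array([1, 2]), np.array([1, 1]))

    def test_youden_tie_breaks_to_smallest_threshold(self):
        # two thresholds reach the same J; the smaller one must be returned
        scores = np.array([10, 20, 5])
        y = np.array([1, 1, 0])
        r = g.roc_from_scores(scores, y)
        assert r.optimal_threshold == 10


class TestEstimator:
    def test_fit_predict_roundtrip(self):
        X = np.array([[150, 3], [120, 9], [40, 2], [60, 1]])
        y = np.array(["tumor", "tumor", "normal", "normal"])
        clf = g.MaxChromosomeThresholdClassifier().fit(X, y)
        assert clf.threshold_ == clf.roc_.optimal_threshold
        assert list(clf.predict(X)) == ["tumor", "tumor", "normal", "normal"]
        assert clf.auc_ == 1.0

    def test_fixed_threshold_and_clone(self):
        X = np.array([[150], [40]])
        y = np.array([1, 0])
        clf = g.MaxChromosomeThresholdClassifier(threshold=200)
        assert clone(clf).get_params()["threshold"] == 200
        clf.fit(X, y)
        assert clf.threshold_ == 200 and list(clf.predict(X)) == [0, 0]


class TestCrossValidation:
    def make_cohort(self, seed=0, gap=True):
        rng = np.random.default_rng(seed)
        n = 15
        Xt = rng.integers(30, 60, size=(n, 23))
        Xt[np.arange(n), rng.integers(0, 23, n)] = rng.integers(150, 300, n)
        Xn = rng.integers(20, 70 if gap else 400, size=(n, 23))
        X = np.vstack([Xt, Xn])
        y = np.array([1] * n + [0] * n)
        return X, y

    def test_seeded_runs_are_identical(self):
        X, y = self.make_cohort()
        a = g.cross_validate_threshold(X, y, seeds=[22, 42])
        b = g.cross_validate_threshold(X, y, seeds=[22, 42])
        pd.testing.assert_frame_equal(a.records, b.records)
        assert a.to_dict() == b.to_dict()

    def test_separable_cohort_gives_unit_auc_and_gap_threshold(self):
        X, y = self.make_cohort()
        rep = g.cross_validate_threshold(X, y)
        assert rep.mean_auc == pytest.approx(1.0)
        lo, hi = X[y == 0].max(axis=1).max(), X[y == 1].max(axis=1).min()
        assert lo < rep.full_cohort_threshold <= hi
        assert (rep.records["threshold"] > lo).all()

    def test_pooled_and_seed_level_aggregations_both_reported(self):
        X, y = self.make_cohort(gap=False)
        rep = g.cross_validate_threshold(X, y)
        assert len(rep.records) == 9
        assert len(rep.seed_mean_auc) == 3
        assert np.isfinite(rep.sd_auc) and np.isfinite(rep.sd_auc_seed_level)

    def test_too_few_samples_per_class_rejected(self):
        with pytest.raises(ValueError):
            g.cross_validate_threshold(np.ones((4, 3)), np.array([1, 1, 0, 0]), folds=3)


class TestMLModels:
    def separable(self, seed=1, n=30):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, size=(n, 23))
        y = np.array([1] * (n // 2) + [0] * (n - n // 2))
        X[y == 1, 4] += 6.0  # one decisive feature
        return X, y

    def test_separable_features_all_algorithms(self):
        X, y = self.separable()
        results = g.evaluate_ml_models(X, y)
        for name, df in results.items():
            assert df["auc"].mean() >= 0.95, name

    def test_permuted_labels_near_chance(self):
        # permutation null averaged over draws; chance label overlap makes a
        # single small-n permutation too noisy to bound tightly
        X, y = self.separable(n=80)
        rng = np.random.default_rng(99)
        aucs = []
        for _ in range(3):
            results = g.evaluate_ml_models(
                X, rng.permutation(y), algorithms=["naive-bayes"]
            )
            aucs.append(results["naive-bayes"]["auc"].mean())
        assert 0.3 <= np.mean(aucs) <= 0.7

    def test_seeded_determinism_and_unknown_algorithm(self):
        X, y = self.separable()
        a = g.evaluate_ml_models(X, y, algorithms=["random-forest"], seeds=[22])
        b = g.evaluate_ml_models(X, y, algorithms=["random-forest"], seeds=[22])
        pd.testing.assert_frame_equal(a["random-forest"], b["random-forest"])
        with pytest.raises(ValueError):
            g.evaluate_ml_models(X, y, algorithms=["quantum-svm"])


class _SingleFeatureModel:
    """Indicator of feature 0 exceeding a threshold; ignores all others."""

    def __init__(self, f=0, t=0.0):
        self.f, self.t = f, t

    def predict_proba(self, X):
        p = (X[:, self.f] > self.t).astype(float)
        return np.column_stack([1 - p, p])


class TestPermutationImportance:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.X = rng.normal(0, 1, size=(60, 5))
        self.y = (self.X[:, 0] > 0).astype(int)

    def test_decisive_feature_ranks_first_and_ignored_near_zero(self):
        model = _SingleFeatureModel()
        imp = g.permutation_importance_auc(model, self.X, self.y, repeats=20, seed=0)
        assert imp[0] >= imp.max() - 1e-12
        assert np.all(np.abs(imp[1:]) < 0.02)

    def test_seeded_repeat_identical(self):
        model = _SingleFeatureModel()
        a = g.permutation_importance_auc(model, self.X, self.y, repeats=5, seed=4)
        b = g.permutation_importance_auc(model, self.X, self.y, repeats=5, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            g.permutation_importance_auc(_SingleFeatureModel(), self.X, np.zeros(60, int))

    def test_agrees_with_sklearn_oracle(self):
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.inspection import permutation_importance as sk_pi
        from sklearn.metrics import roc_auc_score

        model = RandomForestClassifier(n_estimators=50, random_state=0).fit(self.X, self.y)
        ours = g.permutation_importance_auc(model, self.X, self.y, repeats=30, seed=1)
        theirs = sk_pi(
            model, self.X, self.y, n_repeats=30, random_state=1,
            scoring=lambda m, X, y: roc_auc_score(y, m.predict_proba(X)[:, 1]),
        ).importances_mean
        # same statistic, independent permutation streams: agree loosely
        np.testing.assert_allclose(ours, theirs, atol=0.05)
        assert np.argmax(ours) == np.argmax(theirs) == 0


class TestCompositeImportance:
    def test_single_algorithm_formula(self):
        out = g.composite_importance({"nb": np.array([2.0, 1.0, 1.0])}, {"nb": 0.9})
        np.testing.assert_allclose(out, [0.9, 0.45, 0.45])

    def test_additivity_of_identical_algorithms(self):
        raw = {"a": np.array([2.0, 1.0]), "b": np.array([2.0, 1.0])}
        out = g.composite_importance(raw, {"a": 0.8, "b": 0.8})
        np.testing.assert_allclose(out, 2 * g.composite_importance(
            {"a": np.array([2.0, 1.0])}, {"a": 0.8}))

    def test_negatives_floored_and_random_table_oracle(self):
        rng = np.random.default_rng(6)
        raw = {k: rng.normal(0, 1, 7) for k in "abc"}
        med = {k: rng.uniform(0.5, 1.0) for k in "abc"}
        out = g.composite_importance(raw, med)
        expected = np.zeros(7)
        for k in "abc":
            s = np.maximum(raw[k], 0)
            if s.max() > 0:
                expected += s / s.max() * med[k]
        np.testing.assert_allclose(out, expected)

    def test_all_zero_algorithm_contributes_zero(self):
        out = g.composite_importance(
            {"a": np.zeros(3), "b": np.array([1.0, 0.0, 0.0])}, {"a": 0.9, "b": 0.5}
        )
        np.testing.assert_allclose(out, [0.5, 0.0, 0.0])


class TestChrX:
    def test_group_extraction(self):
        normals = pd.DataFrame({"chr1": [5, 6], "chrX": [0, 1]})
        tumors = pd.DataFrame({"chr1": [2, 3], "chrX": [40, 55]})
        out = g.chrx_hcb_compare({"normal": normals, "tumor": tumors})
        assert out == {"normal": [0, 1], "tumor": [40, 55]}

    def test_errors(self):
        ok = pd.DataFrame({"chrX": [1]})
        with pytest.raises(ValueError):
            g.chrx_hcb_compare({"only": ok})
        with pytest.raises(ValueError):
            g.chrx_hcb_compare({"a": ok, "b": pd.DataFrame({"chr1": [1]})})
        with pytest.raises(ValueError):
            g.chrx_hcb_compare({"a": ok, "b": pd.DataFrame({"chrX": []})})

    def test_planted_chrx_clusters_separate_groups(self):
        spec = g.CohortSpec(
            n_tumor=5, n_normal=5,
            genome={f"chr{i}": 1_000_000 for i in range(1, 23)} | {"chrX": 1_000_000},
            n_artifact_bins=100, n_dispersed_hcbs=300,
            tumor_cluster=g.TumorClusterSpec(chrom="chrX", n_bins=150, cpm=40.0),
        )
        co = g.simulate_cohort(spec, 2)
        bl = g.identify_background_bins(co.coverages, co.labels)
        profs = [
            g.chromosome_profile(g.top_k_hcbs(g.apply_blocklist(c, bl), 1000),
                                 co.bins.chrom_names)
            for c in co.coverages
        ]
        table = pd.DataFrame({p.sample_id: p.counts for p in profs}).T
        groups = g.chrx_hcb_compare(
            {"tumor": table.iloc[:5], "normal": table.iloc[5:]}
        )
        assert np.mean(groups["tumor"]) - np.mean(groups["normal"]) > 100
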